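"""Clade tallies by sampling site and co-occurrence (syntopy) by rotting log.

Two divergent mtDNA lineages can be geographically interleaved at two scales:
*sympatry* (both clades present at the same site) and *syntopy* (both clades
inside the same rotting log).  This module reduces a labelled
:class:`~passalus.alignment_io.SampleTable` to per-site clade counts and to
the fraction of multi-individual logs containing both clades.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignment_io import MetadataError, SampleTable

__all__ = ["SiteTally", "SyntopySummary", "tally_by_site", "syntopy_rate"]


@dataclass(frozen=True)
class SiteTally:
    """Per-site and total clade counts."""

    per_site: dict[str, tuple[int, int]]
    n_a: int
    n_b: int
    n: int
    sites_with_a: int
    sites_with_b: int
    pct_a: int
    pct_b: int
    clades: tuple[str, str]

    def to_frame(self) -> pd.DataFrame:
        a, b = self.clades
        return pd.DataFrame(
            [(s, na, nb) for s, (na, nb) in self.per_site.items()],
            columns=["site_id", f"n_clade_{a}", f"n_clade_{b}"],
        )


@dataclass(frozen=True)
class SyntopySummary:
    """Mixed-clade co-occurrence among multi-individual logs."""

    n_multi_logs: int
    n_mixed_logs: int
    fraction: float  # nan when no multi-individual logs

    @property
    def pct(self) -> float:
        return math.nan if math.isnan(self.fraction) else round(100 * self.fraction)


def tally_by_site(table: SampleTable) -> SiteTally:
    """Count individuals of each clade per site and overall.

    Every individual must carry a clade label; unlabelled ids are reported in
    the error.  ``sites_with_X`` counts sites with at least one member of X.
    Percentages are rounded to whole numbers (reporting dialect).
    """
    df = table.df
    unlabelled = df.individual_id[df.clade.isna()].tolist()
    if unlabelled:
        raise MetadataError(f"unlabelled individuals: {unlabelled}")
    clades = tuple(sorted(df.clade.unique()))
    if len(clades) == 1:
        clades = (clades[0], f"not-{clades[0]}")
    a, b = clades[0], clades[1]
    counts = df.groupby(["site_id", "clade"]).size().unstack(fill_value=0)
    for c in (a, b):
        if c not in counts.columns:
            counts[c] = 0
    per_site = {site: (int(row[a]), int(row[b])) for site, row in counts.iterrows()}
    n_a, n_b = int(counts[a].sum()), int(counts[b].sum())
    n = n_a + n_b
    return SiteTally(
        per_site=per_site,
        n_a=n_a,
        n_b=n_b,
        n=n,
        sites_with_a=int((counts[a] > 0).sum()),
        sites_with_b=int((counts[b] > 0).sum()),
        pct_a=round(100 * n_a / n),
        pct_b=round(100 * n_b / n),
        clades=(a, b),
    )


def syntopy_rate(table: SampleTable) -> SyntopySummary:
    """Fraction of multi-individual logs containing both clades.

    Restricted to logs from which >= 2 individuals were sampled; a log is
    mixed iff both clades are present in it.  All rows must carry a
    ``log_id``.  With zero multi-individual logs the fraction is ``nan``.
    """
    df = table.df
    if df.log_id.isna().any():
        missing = df.individual_id[df.log_id.isna()].tolist()
        raise MetadataError(
            f"log_id required for syntopy; missing for: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    unlabelled = df.individual_id[df.clade.isna()].tolist()
    if unlabelled:
        raise MetadataError(f"unlabelled individuals: {unlabelled}")
    by_log = df.groupby("log_id").agg(n=("individual_id", "size"), clades=("clade", "nunique"))
    multi = by_log[by_log.n >= 2]
    n_multi = len(multi)
    n_mixed = int((multi.clades >= 2).sum())
    fraction = math.nan if n_multi == 0 else n_mixed / n_multi
    return SyntopySummary(n_multi_logs=n_multi, n_mixed_logs=n_mixed, fraction=fraction)


def write_summary_json(tally: SiteTally, syntopy: SyntopySummary | None, path: str | Path) -> None:
    """Write totals and syntopy as a small JSON report."""
    a, b = tally.clades
    payload = {
        "totals": {
            f"n_clade_{a}": tally.n_a,
            f"n_clade_{b}": tally.n_b,
            "n": tally.n,
            f"sites_with_{a}": tally.sites_with_a,
            f"sites_with_{b}": tally.sites_with_b,
            f"pct_{a}": tally.pct_a,
            f"pct_{b}": tally.pct_b,
        },
        "syntopy": None
        if syntopy is None
        else {
            "n_multi_logs": syntopy.n_multi_logs,
            "n_mixed_logs": syntopy.n_mixed_logs,
            "fraction": None if math.isnan(syntopy.fraction) else syntopy.fraction,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
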