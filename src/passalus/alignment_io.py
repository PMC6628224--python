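"""Reading, writing and combining aligned mtDNA sequence data and sample metadata.

The substrate for every downstream analysis is an :class:`Alignment`: an
ordered set of equal-length DNA sequences over the IUPAC alphabet (plus the
gap character ``-``), keyed by unique identifiers.  Loci sequenced for
overlapping but non-identical sets of individuals are combined with
:func:`concatenate_loci`, which pads individuals missing a locus with ``N``
over that locus' full span — mirroring the standard practice of coding
missing mitochondrial fragments as undetermined rather than dropping the
individual.

Sample metadata (:class:`SampleTable`) records, per individual, the sampling
site, the rotting log within the site, coordinates, and (optionally) an mtDNA
clade label.  A wide, per-site loader is provided for count tables that give
clade tallies per site rather than one row per individual; it expands such a
table into pseudo-individuals so the tally machinery can consume it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "DETERMINED",
    "GAP",
    "Alignment",
    "SampleTable",
    "AlignmentError",
    "FastaParseError",
    "MetadataError",
    "read_fasta",
    "write_fasta",
    "concatenate_loci",
    "read_metadata",
    "read_site_counts",
    "expand_site_counts",
    "packaged_table2_path",
]

#: IUPAC nucleotide codes (including ambiguity codes and N).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")
#: Fully determined bases.
DETERMINED = frozenset("ACGT")
#: Alignment gap character.
GAP = "-"
_ALPHABET = IUPAC_CODES | {GAP}


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants (e.g. ragged lengths)."""


class FastaParseError(ValueError):
    """Raised on malformed FASTA input (illegal characters, empty files)."""


class MetadataError(ValueError):
    """Raised on malformed or inconsistent sample metadata."""


@dataclass(frozen=True)
class Alignment:
    """An ordered, validated multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in input order.
    sequences
        Upper-case sequences over the IUPAC DNA alphabet plus ``-``; all the
        same length.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment must contain at least one record")
        if len(self.ids) != len(self.sequences):
            raise AlignmentError("ids and sequences differ in number")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(i for i in self.ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise AlignmentError(f"duplicate sequence id {dup!r}")
        ref = len(self.sequences[0])
        for sid, seq in zip(self.ids, self.sequences):
            if len(seq) != ref:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {ref}"
                )
            bad = next((k for k, c in enumerate(seq) if c not in _ALPHABET), None)
            if bad is not None:
                raise FastaParseError(
                    f"illegal character {seq[bad]!r} in record {sid!r} at position {bad + 1}"
                )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        ids, seqs = [], []
        for sid, seq in records:
            ids.append(str(sid))
            seqs.append(str(seq).upper())
        return cls(tuple(ids), tuple(seqs))

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def records(self) -> list[tuple[str, str]]:
        return list(zip(self.ids, self.sequences))

    def get(self, sid: str) -> str:
        try:
            return self.sequences[self.ids.index(sid)]
        except ValueError:
            raise KeyError(sid) from None

    def __contains__(self, sid: str) -> bool:
        return sid in self.ids

    def slice(self, start: int, stop: int) -> "Alignment":
        """Column range ``[start, stop)`` (0-based half-open) as a new alignment."""
        if not (0 <= start <= stop <= self.length):
            raise IndexError(f"slice [{start}, {stop}) outside alignment of length {self.length}")
        return Alignment(self.ids, tuple(s[start:stop] for s in self.sequences))

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment.from_records((i, self.get(i)) for i in ids)


def read_fasta(path: str | Path) -> Alignment:
    """Read a multi-record FASTA file into an :class:`Alignment`.

    Case is normalised to upper.  Raises :class:`FastaParseError` on empty
    input or illegal characters, and :class:`AlignmentError` when records are
    not all the same length.
    """
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return Alignment.from_records(records)


def write_fasta(aln: Alignment, path: str | Path, wrap: int = 70) -> None:
    """Write an alignment as FASTA (default 70-column wrapping)."""
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap or None)
        writer.write_file(recs)


def concatenate_loci(parts: Sequence[Alignment], pad: str = "N") -> Alignment:
    """Concatenate per-locus alignments, padding missing individuals.

    An individual absent from a locus receives ``pad`` characters across that
    locus' full span; output individual order is order of first appearance
    across the parts.  Output length is the sum of part lengths, so slicing
    the result at the part boundaries recovers each part's present records
    exactly.
    """
    if not parts:
        raise AlignmentError("no alignments to concatenate")
    if len(pad) != 1 or pad.upper() not in _ALPHABET:
        raise AlignmentError(f"pad character {pad!r} is not a legal IUPAC code")
    pad = pad.upper()
    order: list[str] = []
    seen: set[str] = set()
    for part in parts:
        for sid in part.ids:
            if sid not in seen:
                seen.add(sid)
                order.append(sid)
    pieces: dict[str, list[str]] = {sid: [] for sid in order}
    for part in parts:
        filler = pad * part.length
        for sid in order:
            pieces[sid].append(part.get(sid) if sid in part else filler)
    return Alignment(tuple(order), tuple("".join(pieces[sid]) for sid in order))


_META_COLUMNS = ["individual_id", "site_id", "log_id", "longitude", "latitude", "clade"]


@dataclass(frozen=True)
class SampleTable:
    """Per-individual sample metadata.

    Wraps a :class:`pandas.DataFrame` with columns ``individual_id``,
    ``site_id``, ``log_id`` (nullable), ``longitude``, ``latitude`` and
    ``clade`` (nullable).  Every ``log_id`` maps to exactly one ``site_id``,
    and clade labels, where present, are drawn from at most two symbols.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise MetadataError(f"metadata missing columns: {missing}")
        if df.empty:
            raise MetadataError("metadata table is empty")
        dups = df.individual_id[df.individual_id.duplicated()].tolist()
        if dups:
            raise MetadataError(f"duplicate individual_id values: {sorted(set(dups))}")
        logged = df.dropna(subset=["log_id"])
        sites_per_log = logged.groupby("log_id")["site_id"].nunique()
        multi = sites_per_log[sites_per_log > 1].index.tolist()
        if multi:
            raise MetadataError(f"log_id mapped to multiple sites: {multi}")
        clades = self.clade_symbols
        if len(clades) > 2:
            raise MetadataError(f"more than two clade symbols present: {sorted(clades)}")

    @property
    def clade_symbols(self) -> frozenset[str]:
        return frozenset(self.df.clade.dropna().unique())

    @property
    def n_individuals(self) -> int:
        return len(self.df)

    def labels(self) -> dict[str, str]:
        """``individual_id -> clade`` for labelled individuals only."""
        labelled = self.df.dropna(subset=["clade"])
        return dict(zip(labelled.individual_id, labelled.clade))

    def with_labels(self, labels: Mapping[str, str]) -> "SampleTable":
        """Return a copy with clade labels overridden from ``labels``."""
        df = self.df.copy()
        df["clade"] = df.individual_id.map(dict(labels)).astype(object)
        return SampleTable(df)


def read_metadata(
    path: str | Path,
    clade_symbols: Sequence[str] | None = None,
) -> SampleTable:
    """Read long-format (one row per individual) metadata CSV/TSV.

    The delimiter is sniffed from the header line.  Empty clade cells become
    missing.  If ``clade_symbols`` is given, any label outside that pair is a
    validation error; otherwise the pair is inferred.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise MetadataError(f"empty metadata file: {path}")
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "site_id": str, "log_id": str})
    for col in ("longitude", "latitude"):
        if col not in df.columns:
            df[col] = float("nan")
    if "log_id" not in df.columns:
        df["log_id"] = pd.NA
    if "clade" not in df.columns:
        df["clade"] = pd.NA
    df["clade"] = df["clade"].where(df["clade"].notna() & (df["clade"].astype(str).str.strip() != ""))
    if clade_symbols is not None:
        allowed = set(clade_symbols)
        bad = set(df.clade.dropna().unique()) - allowed
        if bad:
            raise MetadataError(
                f"clade labels {sorted(bad)} outside the declared pair {sorted(allowed)}"
            )
    return SampleTable(df[_META_COLUMNS].copy())


def read_site_counts(path: str | Path) -> pd.DataFrame:
    """Read a wide per-site count table (one row per site, clade tallies as counts).

    Expected columns: ``site_id``, ``n_logs``, ``longitude``, ``latitude``,
    ``n_clade_a``, ``n_clade_b`` (extra columns are preserved).
    """
    df = pd.read_csv(path, dtype={"site_id": str})
    required = {"site_id", "n_clade_a", "n_clade_b"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"site count table missing columns: {sorted(missing)}")
    if df.site_id.duplicated().any():
        raise MetadataError("duplicate site_id in site count table")
    return df


def expand_site_counts(df: pd.DataFrame, clade_names: tuple[str, str] = ("A", "B")) -> SampleTable:
    """Expand a per-site count table into pseudo-individuals.

    Each counted individual becomes a row with a synthetic id
    ``<site>_<clade><k>``.  Log assignments are not recoverable from per-site
    counts, so ``log_id`` is left missing (syntopy summaries require true
    per-log metadata).
    """
    rows = []
    for rec in df.itertuples(index=False):
        for clade, count in zip(clade_names, (rec.n_clade_a, rec.n_clade_b)):
            for k in range(1, int(count) + 1):
                rows.append(
                    {
                        "individual_id": f"{rec.site_id}_{clade}{k:02d}",
                        "site_id": rec.site_id,
                        "log_id": pd.NA,
                        "longitude": getattr(rec, "longitude", float("nan")),
                        "latitude": getattr(rec, "latitude", float("nan")),
                        "clade": clade,
                    }
                )
    if not rows:
        raise MetadataError("site count table expands to zero individuals")
    return SampleTable(pd.DataFrame(rows, columns=_META_COLUMNS))


def packaged_table2_path() -> Path:
    """Path to the packaged per-site clade count fixture (one row per sampling site)."""
    return Path(str(resources.files("passalus").joinpath("data/table2.csv")))
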