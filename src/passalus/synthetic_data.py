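"""Synthetic two-clade mtDNA datasets with known ground truth.

The generator emulates the statistical structure the analysis stages assume:
a pair of divergent mitochondrial lineages separated by ``k_fixed`` fixed
nucleotide differences, star-like within-clade polymorphism (each individual
carries a Poisson number of private substitutions on its clade's root
haplotype), and a site/log sampling structure in which a target fraction of
multi-individual rotting logs contains both clades (syntopy).  Primer
footprints and restriction enzyme recognition sites can be planted at exact
amplicon coordinates (and scrubbed elsewhere), so the PCR-RFLP design stage
can be exercised against planted truth.

Defaults reproduce the study conditions of the combined beetle dataset:
1069 bp, 123 + 45 individuals (73/27 split), 21 fixed differences and 2.1
expected private substitutions per individual — giving expected
P_between ~ 0.0233, P_within ~ 0.0040 and a divergence ratio expectation of
~6, inside the 5.9-7.5 regime and below the 10x species threshold — across
46 sites and 82 logs with a 10/27 target mixed-log fraction.

The mutation model is substitutions-only (the emulated locus is a gap-free
protein-coding fragment); within-clade variation is star-like rather than
coalescent.  Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .alignment_io import Alignment, SampleTable
from .rflp_design import (
    IUPAC_SETS,
    Enzyme,
    PrimerPair,
    packaged_enzymes,
    reverse_complement,
)

__all__ = [
    "PlantedSite",
    "SimulationParams",
    "SyntheticDataset",
    "ExpectedDivergence",
    "PlantingError",
    "simulate",
    "expected_divergence",
    "write_dataset",
    "rflp_reference_standin",
    "polymorphism_reference_standin",
    "REFERENCE_PRIMERS",
]

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: The published clade-diagnostic COI primer pair (5'->3', each on its own strand).
REFERENCE_PRIMERS = PrimerPair(
    forward="TCTTCAATTATAAATATACGAAC",
    reverse="TTAAAATGTAAACTTCAGGATGTCC",
    name="OdCo1rflp-F/OdCo1rflp-R",
)


class PlantingError(ValueError):
    """Raised when requested planted features are infeasible (overlaps, no room)."""


@dataclass(frozen=True)
class PlantedSite:
    """Plant an enzyme recognition site cutting at ``cut_position`` (top-strand
    cut coordinate within the amplicon) in one clade ("A"/"B") or in "both"."""

    clade: Literal["A", "B", "both"]
    enzyme: Enzyme
    cut_position: int


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; defaults are the emulated study's conditions."""

    seed: int
    length: int = 1069
    n_a: int = 123
    n_b: int = 45
    k_fixed: int = 21
    within_mutations: float = 2.1
    ts_tv_ratio: float = 2.0
    n_sites: int = 46
    n_logs: int = 82
    beetles_per_log: float | None = None  # overrides n_logs when given
    syntopy_fraction: float = 10 / 27
    primer_pair: PrimerPair | None = None
    amplicon_length: int = 244
    amplicon_start: int | None = None
    planted_sites: tuple[PlantedSite, ...] = ()

    def __post_init__(self) -> None:
        if min(self.length, self.n_a, self.n_b) <= 0 or self.k_fixed < 0:
            raise ValueError("length and clade sizes must be positive, k_fixed >= 0")
        if self.within_mutations < 0 or self.ts_tv_ratio <= 0:
            raise ValueError("within_mutations >= 0 and ts_tv_ratio > 0 required")
        if self.planted_sites and self.primer_pair is None:
            raise PlantingError("planted enzyme sites require a planted primer pair")


@dataclass(frozen=True)
class SyntheticDataset:
    """A simulated alignment plus its generating truth."""

    alignment: Alignment
    truth_labels: dict[str, str]
    sample_table: SampleTable
    truth_fixed_sites: tuple[int, ...]  # 1-based alignment positions
    params: SimulationParams


@dataclass(frozen=True)
class ExpectedDivergence:
    """Analytic expectations of the divergence summary under the generator."""

    p_within: float
    p_between: float
    ratio: float


def expected_divergence(params: SimulationParams) -> ExpectedDivergence:
    """Closed-form expectations (to leading order, ignoring multiple hits):

    E[P_within] ~ 2m/L (two independent Poisson(m) private mutation sets),
    E[P_between] ~ (k + 2m)/L, and the ratio of those expectations.
    ``within_mutations == 0`` makes the ratio expectation infinite.
    """
    if params.length <= 0:
        raise ValueError("length must be positive")
    L, k, m = params.length, params.k_fixed, params.within_mutations
    p_within = 2 * m / L
    p_between = (k + 2 * m) / L
    ratio = float("inf") if m == 0 else p_between / p_within
    return ExpectedDivergence(p_within=p_within, p_between=p_between, ratio=ratio)


# ---------------------------------------------------------------------------
# sequence machinery


def _mutate_base(base: str, rng: np.random.Generator, ts_weight: float) -> str:
    """Substitute ``base``: transition with probability ts/(ts+1), else a
    uniform transversion."""
    if rng.random() < ts_weight / (ts_weight + 1.0):
        return _TRANSITION[base]
    return rng.choice(list(_TRANSVERSIONS[base]))


def _realize(pattern: str, rng: np.random.Generator) -> str:
    """Resolve a degenerate IUPAC string to a concrete sequence."""
    return "".join(rng.choice(sorted(IUPAC_SETS[c])) for c in pattern)


def _match_windows(seq: str, enzyme: Enzyme) -> list[tuple[int, int, str]]:
    """(cut, window_start, strand) for every recognition match, top coords."""
    from .rflp_design import _strand_matches  # internal reuse

    L, k = len(seq), len(enzyme.recognition)
    out = []
    for s in _strand_matches(seq, enzyme.recognition):
        cut = s + enzyme.cut_offset
        if 0 < cut < L:
            out.append((cut, s, "+"))
    if not enzyme.palindromic:
        rc = reverse_complement(seq)
        for s in _strand_matches(rc, enzyme.recognition):
            cut = L - (s + enzyme.cut_offset)
            if 0 < cut < L:
                out.append((cut, L - (s + k), "-"))
    return sorted(out)


def _allowed_breakers(enzyme: Enzyme, strand: str, offset: int) -> set[str]:
    """Top-strand bases at window ``offset`` that break the match."""
    k = len(enzyme.recognition)
    if strand == "+":
        keep = IUPAC_SETS[enzyme.recognition[offset]]
    else:
        # bottom-strand match: window offset maps to pattern position k-1-offset,
        # and the pattern constrains the complement of the top-strand base
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        keep = {comp[b] for b in IUPAC_SETS[enzyme.recognition[k - 1 - offset]]}
    return set("ACGT") - set(keep)


# ---------------------------------------------------------------------------
# main generator


def simulate(params: SimulationParams) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset` under ``params`` (seeded).

    Order of operations: draw the ancestral sequence; carve out planted
    primer footprints and enzyme recognition windows (overlaps are an error
    *before* any mutation is applied); place ``k_fixed`` fixed substitutions
    on the clade-B root at free positions; write planted sites per clade and
    scrub accidental recognition matches inside the amplicon; draw each
    individual's private substitutions at free positions; assemble the
    site/log sampling table targeting the syntopy fraction in expectation.
    """
    rng = np.random.default_rng(params.seed)
    L = params.length
    anc = rng.choice(_BASES, size=L)
    feature = np.zeros(L, dtype=bool)

    # --- planted primer frame
    astart = aend = None
    plant_instructions: list[tuple[PlantedSite, int, str]] = []  # (site, abs_start, realized)
    if params.primer_pair is not None:
        pp = params.primer_pair
        if params.amplicon_length > L:
            raise PlantingError("amplicon longer than sequence")
        astart = (L - params.amplicon_length) // 2 if params.amplicon_start is None else params.amplicon_start
        aend = astart + params.amplicon_length
        if astart < 0 or aend > L:
            raise PlantingError("amplicon frame outside sequence")
        fwd = _realize(pp.forward, rng)
        rev_rc = _realize(reverse_complement(pp.reverse), rng)
        anc[astart : astart + len(fwd)] = list(fwd)
        anc[aend - len(rev_rc) : aend] = list(rev_rc)
        feature[astart : astart + len(fwd)] = True
        feature[aend - len(rev_rc) : aend] = True

        for ps in params.planted_sites:
            start = astart + ps.cut_position - ps.enzyme.cut_offset
            window = slice(start, start + len(ps.enzyme.recognition))
            if start < astart or window.stop > aend:
                raise PlantingError(
                    f"planted {ps.enzyme.name} site (cut {ps.cut_position}) falls outside the amplicon"
                )
            if feature[window].any():
                raise PlantingError(
                    f"planted {ps.enzyme.name} site at cut {ps.cut_position} overlaps another feature"
                )
            realized = _realize(ps.enzyme.recognition, rng)
            plant_instructions.append((ps, start, realized))
            feature[window] = True

    # --- fixed differences between clade roots
    free = np.flatnonzero(~feature)
    if params.k_fixed > len(free):
        raise PlantingError("k_fixed exceeds the number of non-feature positions")
    fixed_pos = np.sort(rng.choice(free, size=params.k_fixed, replace=False))
    root_a = anc.copy()
    root_b = anc.copy()
    for p in fixed_pos:
        root_b[p] = _mutate_base(str(root_a[p]), rng, params.ts_tv_ratio)

    # --- write planted sites per clade; break them in the excluded clade
    for ps, start, realized in plant_instructions:
        window = slice(start, start + len(realized))
        for root in (root_a, root_b):
            root[window] = list(realized)
        if ps.clade != "both":
            excluded = root_b if ps.clade == "A" else root_a
            offset = _pick_break_offset(ps.enzyme)
            breakers = sorted(_allowed_breakers(ps.enzyme, "+", offset))
            excluded[start + offset] = rng.choice(breakers)

    if astart is not None:
        _scrub_amplicon(
            (root_a, root_b), anc, astart, aend, params, plant_instructions, feature, fixed_pos, rng
        )

    # --- individuals
    roots = {"A": root_a, "B": root_b}
    sizes = {"A": params.n_a, "B": params.n_b}
    mutable = np.flatnonzero(~feature & ~np.isin(np.arange(L), fixed_pos))
    ids: list[str] = []
    seqs: list[str] = []
    labels: dict[str, str] = {}
    for clade in ("A", "B"):
        width = len(str(sizes[clade]))
        for i in range(1, sizes[clade] + 1):
            sid = f"{clade}{i:0{width}d}"
            seq = roots[clade].copy()
            n_mut = rng.poisson(params.within_mutations)
            n_mut = min(n_mut, len(mutable))
            if n_mut:
                for p in rng.choice(mutable, size=n_mut, replace=False):
                    seq[p] = _mutate_base(str(seq[p]), rng, params.ts_tv_ratio)
            ids.append(sid)
            seqs.append("".join(seq))
            labels[sid] = clade

    alignment = Alignment(tuple(ids), tuple(seqs))
    truth_fixed = tuple(int(p) + 1 for p in np.flatnonzero(root_a != root_b))
    table = _sample_structure(ids, labels, params, rng)
    return SyntheticDataset(
        alignment=alignment,
        truth_labels=labels,
        sample_table=table,
        truth_fixed_sites=truth_fixed,
        params=params,
    )


def _pick_break_offset(enzyme: Enzyme) -> int:
    """Window offset whose pattern letter is most constrained (breakable)."""
    sizes = [len(IUPAC_SETS[c]) for c in enzyme.recognition]
    best = min(range(len(sizes)), key=lambda i: sizes[i])
    if sizes[best] == 4:
        raise PlantingError(f"{enzyme.name} recognition is all-N; cannot plant its absence")
    return best


def _scrub_amplicon(
    roots: tuple[np.ndarray, np.ndarray],
    anc: np.ndarray,
    astart: int,
    aend: int,
    params: SimulationParams,
    plants: list[tuple[PlantedSite, int, str]],
    feature: np.ndarray,
    fixed_pos: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Disrupt accidental recognition matches of planted enzymes inside the
    amplicon, editing all roots identically at free positions so no spurious
    fixed difference is introduced."""
    enzymes = {ps.enzyme.name: ps.enzyme for ps, _, _ in plants}
    exp: dict[str, dict[str, set[int]]] = {"A": {}, "B": {}}
    for ps, _, _ in plants:
        clades = ("A", "B") if ps.clade == "both" else (ps.clade,)
        for c in clades:
            exp[c].setdefault(ps.enzyme.name, set()).add(ps.cut_position)
    blocked = feature.copy()
    blocked[fixed_pos] = True
    for _ in range(1000):
        dirty = False
        for ci, root in enumerate(roots):
            clade = "AB"[ci]
            amp = "".join(root[astart:aend])
            for name, enz in enzymes.items():
                want = exp[clade].get(name, set())
                for cut, wstart, strand in _match_windows(amp, enz):
                    if cut in want:
                        continue
                    _disrupt(roots, anc, astart + wstart, enz, strand, blocked, rng)
                    dirty = True
                    break
                if dirty:
                    break
            if dirty:
                break
        if not dirty:
            break
    else:
        raise PlantingError("could not scrub accidental recognition sites")
    # planted sites must have survived
    for ci, root in enumerate(roots):
        clade = "AB"[ci]
        amp = "".join(root[astart:aend])
        for name, enz in enzymes.items():
            found = {cut for cut, _, _ in _match_windows(amp, enz)}
            want = exp[clade].get(name, set())
            if not want <= found or (found - want):
                raise PlantingError(
                    f"planted {name} layout unsatisfiable for clade {clade} "
                    f"(wanted cuts {sorted(want)}, found {sorted(found)})"
                )


def _disrupt(
    roots: tuple[np.ndarray, np.ndarray],
    anc: np.ndarray,
    abs_start: int,
    enzyme: Enzyme,
    strand: str,
    blocked: np.ndarray,
    rng: np.random.Generator,
) -> int:
    k = len(enzyme.recognition)
    for off in range(k):
        pos = abs_start + off
        if blocked[pos]:
            continue
        breakers = sorted(_allowed_breakers(enzyme, strand, off))
        if not breakers:
            continue
        new = rng.choice(breakers)
        for arr in (*roots, anc):
            arr[pos] = new
        return pos
    raise PlantingError(
        f"accidental {enzyme.name} site at {abs_start} overlaps only protected positions"
    )


# ---------------------------------------------------------------------------
# sampling structure


def _sample_structure(
    ids: Sequence[str],
    labels: dict[str, str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> SampleTable:
    n = len(ids)
    n_logs = params.n_logs
    if params.beetles_per_log is not None:
        n_logs = max(1, round(n / params.beetles_per_log))
    n_logs = min(n_logs, n)
    # study-region bounding box (southern Appalachians + northern Mississippi)
    site_ids = [f"S{i + 1:02d}" for i in range(params.n_sites)]
    lons = rng.uniform(-90.0, -78.0, size=params.n_sites)
    lats = rng.uniform(33.2, 39.6, size=params.n_sites)
    site_order = rng.permutation(params.n_sites)
    log_site = {f"L{i + 1:02d}": site_ids[site_order[i % params.n_sites]] for i in range(n_logs)}
    log_ids = sorted(log_site)

    counts = np.ones(n_logs, dtype=int)
    extra = n - n_logs
    if extra > 0:
        counts += rng.multinomial(extra, np.full(n_logs, 1.0 / n_logs))

    pools = {
        "A": [i for i in ids if labels[i] == "A"],
        "B": [i for i in ids if labels[i] == "B"],
    }
    for pool in pools.values():
        rng.shuffle(pool)

    def take(clade: str) -> str | None:
        return pools[clade].pop() if pools[clade] else None

    def take_any() -> str | None:
        weights = [len(pools["A"]), len(pools["B"])]
        if sum(weights) == 0:
            return None
        clade = rng.choice(["A", "B"], p=np.array(weights) / sum(weights))
        return take(clade)

    # decide which multi-individual logs will be mixed, and reserve one member
    # of each clade for them up front so the smaller clade's pool cannot be
    # drained by single-clade logs first (which would bias the realised
    # syntopy fraction downward)
    members_by_log: dict[str, list[str]] = {log: [] for log in log_ids}
    multi = [log for log, c in zip(log_ids, counts) if c >= 2]
    mixed = [log for log in multi if rng.random() < params.syntopy_fraction]
    for log in mixed:
        for clade in ("A", "B"):
            m = take(clade)
            if m is not None:
                members_by_log[log].append(m)
    rows = []
    for log, count in zip(log_ids, counts):
        members = members_by_log[log]
        if count >= 2 and log not in mixed:
            clade = rng.choice(["A", "B"], p=_pool_weights(pools))
            while len(members) < count and pools[clade]:
                members.append(take(clade))
        while len(members) < count:
            m = take_any()
            if m is None:
                break
            members.append(m)
        site = log_site[log]
        k = site_ids.index(site)
        for m in members:
            rows.append(
                {
                    "individual_id": m,
                    "site_id": site,
                    "log_id": log,
                    "longitude": round(float(lons[k]), 5),
                    "latitude": round(float(lats[k]), 5),
                    "clade": labels[m],
                }
            )
    # any leftovers (pool exhaustion edge cases) go to the last log
    for clade in ("A", "B"):
        while pools[clade]:
            m = pools[clade].pop()
            site = log_site[log_ids[-1]]
            k = site_ids.index(site)
            rows.append(
                {
                    "individual_id": m,
                    "site_id": site,
                    "log_id": log_ids[-1],
                    "longitude": round(float(lons[k]), 5),
                    "latitude": round(float(lats[k]), 5),
                    "clade": labels[m],
                }
            )
    df = pd.DataFrame(rows).sort_values("individual_id", kind="stable").reset_index(drop=True)
    return SampleTable(df)


def _pool_weights(pools: dict[str, list[str]]) -> np.ndarray:
    w = np.array([len(pools["A"]), len(pools["B"])], dtype=float)
    if w.sum() == 0:
        return np.array([0.5, 0.5])
    return w / w.sum()


# ---------------------------------------------------------------------------
# artifacts


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + metadata CSV + truth JSON; returns the paths."""
    from .alignment_io import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": outdir / "alignment.fasta",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.alignment, paths["alignment"])
    ds.sample_table.df.to_csv(paths["metadata"], index=False)
    paths["truth"].write_text(
        json.dumps(
            {
                "labels": ds.truth_labels,
                "fixed_sites_1based": list(ds.truth_fixed_sites),
                "seed": ds.params.seed,
            },
            indent=2,
        )
        + "\n"
    )
    return paths


def polymorphism_reference_standin(seed: int = 0) -> tuple[Alignment, dict[str, int]]:
    """SYNTHETIC stand-in for the legacy 25-haplotype COI alignment.

    The real haplotypes live in GenBank and are not bundled; this stand-in
    plants the *printed polymorphism level* of that dataset as ground truth:
    25 sequences of 1097 bp with exactly 41 segregating sites, 28 of which
    are parsimony-informative (minor state in 2-23 sequences) and 13
    singletons.  The site counters must recompute those planted totals from
    the sequence data.  Returns the alignment and the planted truth
    ``{"S": 41, "S_pi": 28}``.
    """
    rng = np.random.default_rng(seed)
    n, length, s_total, s_informative = 25, 1097, 41, 28
    anc = rng.choice(_BASES, size=length)
    cols = rng.choice(length, size=s_total, replace=False)
    seqs = np.tile(anc, (n, 1))
    for idx, col in enumerate(cols):
        alt = _mutate_base(str(anc[col]), rng, 2.0)
        k = int(rng.integers(2, n - 1)) if idx < s_informative else 1
        rows = rng.choice(n, size=k, replace=False)
        seqs[rows, col] = alt
    aln = Alignment(
        tuple(f"hap{i + 1:02d}" for i in range(n)),
        tuple("".join(row) for row in seqs),
    )
    return aln, {"S": s_total, "S_pi": s_informative}


def rflp_reference_standin(seed: int = 0) -> SyntheticDataset:
    """SYNTHETIC stand-in for the published haplotype set behind the
    clade-diagnostic assay.

    The true haplotype sequences live in GenBank and are not bundled; this
    stand-in carries the *published printed facts* instead: the OdCo1rflp
    primer footprints framing a 244-bp amplicon, a TaqI site shared by both
    clades cutting at coordinate 103, an extra clade-B TaqI site cutting at
    80, a clade-A BsaI (Type IIS) site cutting at 68 and a clade-B DdeI site
    cutting at 108 — the cut layout implied by the published expected
    fragment sizes (clade A: TaqI 103/141, BsaI+DdeI 68/176; clade B: TaqI
    23/80/141, BsaI+DdeI 108/136).  Digesting this stand-in through the
    design pipeline must *recompute* those patterns.
    """
    enz = {e.name: e for e in packaged_enzymes()}
    params = SimulationParams(
        seed=seed,
        length=364,
        n_a=2,
        n_b=2,
        k_fixed=6,
        within_mutations=0.0,
        n_sites=2,
        n_logs=4,
        primer_pair=REFERENCE_PRIMERS,
        amplicon_length=244,
        amplicon_start=60,
        planted_sites=(
            PlantedSite("both", enz["TaqI"], 103),
            PlantedSite("B", enz["TaqI"], 80),
            PlantedSite("A", enz["BsaI"], 68),
            PlantedSite("B", enz["DdeI"], 108),
        ),
    )
    return simulate(params)
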