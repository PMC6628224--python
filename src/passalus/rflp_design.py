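"""In-silico PCR-RFLP assay design for distinguishing two mtDNA clades.

Workflow (mirroring how diagnostic restriction assays are designed in
practice):

1. build a per-clade IUPAC consensus of the labelled alignment;
2. list *fixed differences* — alignment columns where the two clades carry
   disjoint single determined states in every (determined) member;
3. extract the amplicon delimited by a degenerate primer pair from each
   haplotype;
4. scan amplicons for restriction enzyme recognition sites on both strands
   (Type IIS offsets supported) and simulate the digest;
5. enumerate single enzymes and enzyme pairs whose digests are uniform
   within each clade and distinguishable between clades on a gel, and rank
   them by gel interpretability.

Coordinate conventions: internal positions are 0-based half-open; a "cut
coordinate" is the number of top-strand bases to the left of the scissile
position, so fragment lengths are successive differences of
``{0, cuts..., length}`` (sticky-end overhangs are ignored; gel band
positions track top-strand lengths).  Reported positions are 1-based.
"""

from __future__ import annotations

import csv
import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .alignment_io import Alignment, IUPAC_CODES

__all__ = [
    "Enzyme",
    "PrimerPair",
    "FragmentPattern",
    "DiagnosticSite",
    "GelParams",
    "AssayDesign",
    "NoAmplificationError",
    "NoDiagnosticSiteError",
    "reverse_complement",
    "load_enzyme_table",
    "packaged_enzymes",
    "read_primer_pair",
    "clade_consensus",
    "fixed_differences",
    "extract_amplicon",
    "scan_recognition_sites",
    "digest",
    "design_assays",
    "expected_fragment_table",
]

logger = logging.getLogger(__name__)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC_SETS.items()}


class NoAmplificationError(ValueError):
    """Raised when a primer has no binding site, or sites are incompatible."""


class NoDiagnosticSiteError(ValueError):
    """Raised when no fixed difference separates the clades."""


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (``R`` -> ``Y`` etc.)."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: degenerate recognition site + top-strand cut offset.

    ``cut_offset`` is relative to the recognition start and may exceed the
    recognition length for Type IIS enzymes that cut downstream.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError("empty recognition sequence")
        bad = set(self.recognition.upper()) - IUPAC_CODES
        if bad:
            raise ValueError(f"illegal recognition characters {sorted(bad)} in {self.name}")
        object.__setattr__(self, "recognition", self.recognition.upper())

    @property
    def palindromic(self) -> bool:
        return self.recognition == reverse_complement(self.recognition)


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; both primers written 5'->3' on their own strand."""

    forward: str
    reverse: str
    max_mismatch: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for label, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValueError(f"{label} primer shorter than 15 nt")
            bad = set(p.upper()) - IUPAC_CODES
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)} in {label} primer")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())


@dataclass(frozen=True)
class FragmentPattern:
    """Digest product: fragment lengths (positional order) and their cut coordinates."""

    fragments: tuple[int, ...]
    source_cuts: tuple[int, ...]
    length: int

    def __post_init__(self) -> None:
        assert sum(self.fragments) == self.length, "fragments must sum to amplicon length"
        assert tuple(sorted(self.source_cuts)) == self.source_cuts

    @property
    def sorted_fragments(self) -> tuple[int, ...]:
        return tuple(sorted(self.fragments))

    def render(self) -> str:
        """Gel-table cell: sizes joined ``a/b/c`` ascending."""
        return "/".join(str(f) for f in self.sorted_fragments)


@dataclass(frozen=True)
class DiagnosticSite:
    """A fixed difference between clades.  ``position`` is 1-based."""

    position: int
    state_by_clade: dict[str, str]


@dataclass(frozen=True)
class GelParams:
    """Resolution limits of the agarose gel used to read the assay."""

    min_visible_bp: int = 20
    min_separation_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.min_visible_bp < 0 or self.min_separation_pct < 0:
            raise ValueError("gel parameters must be >= 0")


@dataclass(frozen=True)
class AssayDesign:
    """A candidate diagnostic assay and its per-clade expected banding."""

    primer_pair: PrimerPair
    enzymes: tuple[Enzyme, ...]
    pattern_by_clade: dict[str, FragmentPattern]
    diagnostic: bool
    gel_report: dict[str, tuple[int, ...]]  # visible bands per clade, ascending

    @property
    def name(self) -> str:
        return "+".join(e.name for e in self.enzymes)


# ---------------------------------------------------------------------------
# enzyme / primer I/O


def load_enzyme_table(path: str | Path) -> list[Enzyme]:
    """Read a flat TSV ``name<TAB>recognition<TAB>cut_offset`` (``#`` comments)."""
    enzymes = []
    with open(path) as fh:
        reader = csv.reader((ln for ln in fh if ln.strip() and not ln.startswith("#")), delimiter="\t")
        header = next(reader)
        if [h.strip().lower() for h in header[:3]] != ["name", "recognition", "cut_offset"]:
            raise ValueError(f"unexpected enzyme table header: {header}")
        for row in reader:
            enzymes.append(Enzyme(row[0].strip(), row[1].strip(), int(row[2])))
    if not enzymes:
        raise ValueError(f"no enzymes in {path}")
    return enzymes


def packaged_enzymes() -> list[Enzyme]:
    """The packaged enzyme set (TaqI, BsaI, DdeI)."""
    return load_enzyme_table(str(resources.files("passalus").joinpath("data/enzymes.tsv")))


def read_primer_pair(path: str | Path, max_mismatch: int = 0) -> PrimerPair:
    """Read a primer pair from two-line plain text or a two-record FASTA.

    Order: forward first, reverse second.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        seqs, names = [], []
        for ln in lines:
            if ln.startswith(">"):
                seqs.append("")
                names.append(ln[1:].split()[0] if len(ln) > 1 else "")
            else:
                seqs[-1] += ln
        primers = seqs
        name = "/".join(names)
    else:
        primers, name = lines, ""
    if len(primers) != 2:
        raise ValueError(f"expected exactly 2 primers in {path}, got {len(primers)}")
    return PrimerPair(primers[0], primers[1], max_mismatch=max_mismatch, name=name)


# ---------------------------------------------------------------------------
# consensus and fixed differences


def _determined_states(column: Iterable[str]) -> set[str]:
    return {c for c in column if c in "ACGT"}


def clade_consensus(aln: Alignment, labels: Mapping[str, str]) -> dict[str, str]:
    """Per-clade IUPAC consensus: the code for the union of determined states
    observed at each column (columns with no determined state become ``N``)."""
    clades = sorted(set(labels.values()))
    out: dict[str, str] = {}
    for clade in clades:
        ids = [i for i in aln.ids if labels.get(i) == clade]
        if not ids:
            raise ValueError(f"clade {clade!r} has no members in the alignment")
        seqs = [aln.get(i) for i in ids]
        cons = []
        for col in zip(*seqs):
            states = _determined_states(col)
            cons.append(_SET_TO_CODE[frozenset(states)] if states else "N")
        out[clade] = "".join(cons)
    return out


def fixed_differences(aln: Alignment, labels: Mapping[str, str]) -> list[DiagnosticSite]:
    """Columns where the clades carry disjoint singleton determined-state sets.

    Members whose state at a column is undetermined are excluded from the
    test at that column rather than vetoing it (alignments padded with N
    would otherwise veto every site).  Positions are reported 1-based.
    """
    clades = sorted(set(labels.values()))
    if len(clades) != 2:
        raise ValueError(f"need exactly two clades, got {clades}")
    members = {c: [aln.get(i) for i in aln.ids if labels.get(i) == c] for c in clades}
    sites: list[DiagnosticSite] = []
    for pos in range(aln.length):
        states = {c: _determined_states(s[pos] for s in members[c]) for c in clades}
        sa, sb = states[clades[0]], states[clades[1]]
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            sites.append(
                DiagnosticSite(
                    position=pos + 1,
                    state_by_clade={clades[0]: next(iter(sa)), clades[1]: next(iter(sb))},
                )
            )
    return sites


# ---------------------------------------------------------------------------
# amplicon extraction


def _primer_mismatches(template: str, start: int, primer: str) -> int:
    """IUPAC-incompatible positions between a primer and the template window.

    A position is compatible when the base sets intersect (degenerate primer
    letters bind any base in their set; N in the template binds anything).
    """
    mm = 0
    for k, p in enumerate(primer):
        t = template[start + k]
        if t == "-" or not (IUPAC_SETS[p] & IUPAC_SETS.get(t, frozenset())):
            mm += 1
    return mm


def _primer_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    k = len(primer)
    return [
        s
        for s in range(len(template) - k + 1)
        if _primer_mismatches(template, s, primer) <= max_mismatch
    ]


def extract_amplicon(seq: str, primers: PrimerPair) -> str:
    """Extract the PCR product delimited by a primer pair from a template.

    The forward primer is matched on the top strand; the reverse primer as
    its reverse complement downstream of the forward site.  The amplicon
    spans the forward primer start through the end of the reverse footprint
    (both primers included in the length).  Among valid pairs the smallest
    product is chosen (ties: leftmost forward site).
    """
    seq = seq.upper()
    f_sites = _primer_sites(seq, primers.forward, primers.max_mismatch)
    if not f_sites:
        raise NoAmplificationError("forward primer has no binding site")
    rc_rev = reverse_complement(primers.reverse)
    r_sites = _primer_sites(seq, rc_rev, primers.max_mismatch)
    if not r_sites:
        raise NoAmplificationError("reverse primer has no binding site")
    candidates = [
        (r + len(rc_rev) - f, f, r)
        for f in f_sites
        for r in r_sites
        if r >= f + len(primers.forward)
    ]
    if not candidates:
        raise NoAmplificationError(
            "primer sites overlap or are out of order; no valid amplicon"
        )
    _, f, r = min(candidates)
    return seq[f : r + len(rc_rev)]


# ---------------------------------------------------------------------------
# restriction digestion


def _site_compatible(seq_char: str, pattern_char: str) -> bool:
    """Conservative matching: every expansion of the sequence base must fit
    the recognition letter (i.e. set(seq) is a subset of set(pattern))."""
    s = IUPAC_SETS.get(seq_char)
    return s is not None and s <= IUPAC_SETS[pattern_char]


def _strand_matches(seq: str, pattern: str) -> list[int]:
    k = len(pattern)
    return [
        s
        for s in range(len(seq) - k + 1)
        if all(_site_compatible(seq[s + i], pattern[i]) for i in range(k))
    ]


def scan_recognition_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted top-strand cut coordinates for one enzyme.

    The top strand is scanned directly; for non-palindromic recognitions the
    bottom strand is scanned via the reverse complement, and each bottom
    match's cut is mapped back to the top-strand coordinate
    ``L - (match_start + cut_offset)``.  Cuts falling on or outside the
    sequence boundaries are discarded; duplicates are merged.
    """
    seq = seq.upper()
    L = len(seq)
    cuts: set[int] = set()
    for s in _strand_matches(seq, enzyme.recognition):
        cut = s + enzyme.cut_offset
        if 0 < cut < L:
            cuts.add(cut)
    if not enzyme.palindromic:
        rc = reverse_complement(seq)
        for s in _strand_matches(rc, enzyme.recognition):
            cut = L - (s + enzyme.cut_offset)
            if 0 < cut < L:
                cuts.add(cut)
    return sorted(cuts)


def digest(amplicon: str, enzymes: Sequence[Enzyme]) -> FragmentPattern:
    """Simulate a (co-)digest: union of all enzymes' cuts, fragments as
    successive differences.  No recognition site yields one full-length
    fragment."""
    if not amplicon:
        raise ValueError("empty amplicon")
    L = len(amplicon)
    cuts = sorted(set(itertools.chain.from_iterable(scan_recognition_sites(amplicon, e) for e in enzymes)))
    bounds = [0, *cuts, L]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentPattern(fragments=fragments, source_cuts=tuple(cuts), length=L)


# ---------------------------------------------------------------------------
# assay search


def _visible_bands(pattern: FragmentPattern, gel: GelParams) -> tuple[int, ...]:
    return tuple(sorted(f for f in pattern.sorted_fragments if f >= gel.min_visible_bp))


def _distinguishable(a: tuple[int, ...], b: tuple[int, ...], gel: GelParams) -> bool:
    """Two visible band sets are distinguishable if their counts differ, or
    any size-ordered band pair differs by more than the gel's separation
    threshold (relative to the larger band)."""
    if len(a) != len(b):
        return True
    thr = gel.min_separation_pct / 100.0
    return any(x != y and abs(x - y) / max(x, y) > thr for x, y in zip(a, b))


def design_assays(
    aln: Alignment,
    labels: Mapping[str, str],
    enzyme_db: Sequence[Enzyme],
    primers: PrimerPair,
    gel: GelParams = GelParams(),
    pair_search: bool = True,
) -> list[AssayDesign]:
    """Enumerate diagnostic single- and double-enzyme assays, best first.

    Every haplotype's amplicon is digested with every candidate enzyme (and
    every unordered enzyme pair when ``pair_search``).  A design is kept when
    each clade's haplotypes give one uniform pattern and the two clades'
    gel-filtered band sets are distinguishable.  Ranking: larger smallest
    visible band first, then larger between-clade band-count difference,
    then fewer enzymes, then enzyme name.

    Sequences whose amplicon cannot be extracted (e.g. padded records whose
    primer region is all N) are excluded and logged; each clade needs at
    least one amplifiable member.
    """
    if not fixed_differences(aln, labels):
        raise NoDiagnosticSiteError("no fixed nucleotide difference between clades")
    if not enzyme_db:
        raise ValueError("empty enzyme database")
    clades = sorted(set(labels.values()))
    amplicons: dict[str, list[str]] = {c: [] for c in clades}
    for sid in aln.ids:
        clade = labels.get(sid)
        if clade is None:
            continue
        try:
            amp = extract_amplicon(aln.get(sid), primers)
        except NoAmplificationError as e:
            logger.info("excluding %s from assay search (%s)", sid, e)
            continue
        if amp not in amplicons[clade]:
            amplicons[clade].append(amp)
    for c in clades:
        if not amplicons[c]:
            raise NoAmplificationError(f"no amplifiable member in clade {c!r}")

    candidates: list[tuple[Enzyme, ...]] = [(e,) for e in enzyme_db]
    if pair_search:
        candidates += [tuple(p) for p in itertools.combinations(enzyme_db, 2)]

    designs: list[AssayDesign] = []
    for enzymes in candidates:
        patterns: dict[str, FragmentPattern] = {}
        uniform = True
        for c in clades:
            digests = {d.sorted_fragments: d for d in (digest(a, enzymes) for a in amplicons[c])}
            if len(digests) != 1:
                uniform = False
                break
            patterns[c] = next(iter(digests.values()))
        if not uniform:
            continue
        bands = {c: _visible_bands(patterns[c], gel) for c in clades}
        if not _distinguishable(bands[clades[0]], bands[clades[1]], gel):
            continue
        designs.append(
            AssayDesign(
                primer_pair=primers,
                enzymes=enzymes,
                pattern_by_clade=patterns,
                diagnostic=True,
                gel_report=bands,
            )
        )

    def rank(d: AssayDesign) -> tuple:
        min_band = min((min(b) for b in d.gel_report.values() if b), default=0)
        count_diff = abs(len(d.gel_report[clades[0]]) - len(d.gel_report[clades[1]]))
        return (-min_band, -count_diff, len(d.enzymes), d.name)

    return sorted(designs, key=rank)


def expected_fragment_table(designs: Sequence[AssayDesign]) -> pd.DataFrame:
    """Expected-fragment report: rows = clades, one column per assay,
    cells = fragment sizes joined ``a/b/c`` ascending."""
    if not designs:
        raise ValueError("no assay designs to report")
    clades = sorted(designs[0].pattern_by_clade)
    data = {
        f"{d.name} digest": [d.pattern_by_clade[c].render() for c in clades] for d in designs
    }
    return pd.DataFrame(data, index=[f"Clade {c}" for c in clades])


def assay_report_json(designs: Sequence[AssayDesign], path: str | Path) -> None:
    """Machine-readable assay report."""
    payload = [
        {
            "enzymes": [e.name for e in d.enzymes],
            "primer_forward": d.primer_pair.forward,
            "primer_reverse": d.primer_pair.reverse,
            "diagnostic": d.diagnostic,
            "patterns": {
                c: {
                    "fragments": list(p.sorted_fragments),
                    "cuts_after_position": list(p.source_cuts),
                    "amplicon_length": p.length,
                }
                for c, p in d.pattern_by_clade.items()
            },
            "visible_bands": {c: list(b) for c, b in d.gel_report.items()},
        }
        for d in designs
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
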