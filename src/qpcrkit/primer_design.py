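"""SNP-anchored primer enumeration and assay assembly.

A copy-specific qPCR primer places a homolog-discriminating SNP at its 3'
terminus, so that polymerase extension fails on the non-target copy.  Under
optimized cycling conditions this single terminal mismatch is enough to
discriminate homologs that are otherwise nearly identical.

The designer enumerates every primer window whose 3' end sits on a SNP, on
both strands, filters on length (20-23 nt), GC content (45-55%), and
homopolymer runs (no run longer than 4), then assembles forward x reverse
combinations into amplicons of 85-125 bp (measured on the plus strand,
including both primers) that retain at least one additional SNP between the
primer 3' ends.  When homolog structure makes an in-bounds amplicon
impossible the upper bound may be relaxed up to ``extension_cap``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .seq_homology import HomologSet, SNPSite, SeqRecord, call_snps

__all__ = [
    "DesignParams",
    "PrimerCandidate",
    "PrimerPair",
    "PrimerSearchWarning",
    "gc_content",
    "has_homopolymer",
    "reverse_complement",
    "enumerate_anchored_primers",
    "assemble_pairs",
    "design_assay",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PrimerSearchWarning(UserWarning):
    """Raised (as a warning) when no candidate survives the filters.

    Carries per-constraint rejection counts in ``counts``.
    """

    def __init__(self, message: str, counts: dict[str, int]):
        super().__init__(message)
        self.counts = counts


@dataclass(frozen=True)
class DesignParams:
    """Constraint set for SNP-anchored primer design.

    Lengths in nucleotides, GC bounds in percent, amplicon bounds in base
    pairs (plus-strand span including both primers).
    """

    len_min: int = 20
    len_max: int = 23
    gc_min: float = 45.0
    gc_max: float = 55.0
    max_homopolymer: int = 4
    amplicon_min: int = 85
    amplicon_max: int = 125
    require_3prime_snp: bool = True
    prefer_terminal_gc: bool = True
    allow_amplicon_extension: bool = True
    extension_cap: int = 200

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise ValueError("len_min must be <= len_max")
        if not (self.amplicon_min <= self.amplicon_max <= self.extension_cap):
            raise ValueError("require amplicon_min <= amplicon_max <= extension_cap")


@dataclass(frozen=True)
class PrimerCandidate:
    """An oligo anchored on a SNP, written 5'->3'.

    ``template_start``/``template_end`` are 0-based half-open on the plus
    strand of the query cDNA.  For strand "-", ``seq`` is the reverse
    complement of the template slice and the 3' terminal base sits at
    ``template_start`` on the plus strand.
    """

    seq: str
    strand: str
    template_start: int
    template_end: int
    gc_percent: float
    anchored_snps: tuple[SNPSite, ...]
    terminal_base: str

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def anchor_pos(self) -> int:
        """Plus-strand position of the 3' terminal base."""
        return self.template_end - 1 if self.strand == "+" else self.template_start

    @property
    def three_prime_end(self) -> int:
        return self.anchor_pos


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_len: int
    interior_snp_count: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.forward.strand != "+" or self.reverse.strand != "-":
            raise ValueError("pair requires a + forward and a - reverse")


def gc_content(seq: str) -> float:
    """Percent G+C of a DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def has_homopolymer(seq: str, max_run: int = 4) -> bool:
    """True iff some single-base run is longer than ``max_run``."""
    if not seq:
        raise ValueError("empty sequence")
    run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        if run > max_run:
            return True
    return False


def enumerate_anchored_primers(
    template: SeqRecord,
    snps: Sequence[SNPSite],
    params: DesignParams = DesignParams(),
    strand: str = "+",
) -> list[PrimerCandidate]:
    """Enumerate all primers of each allowed length with a SNP at the 3' end.

    For strand "+" the window ends at ``query_pos + 1``; for strand "-" it
    starts at ``query_pos`` and the emitted sequence is the reverse
    complement of the slice.  Candidates violating length bounds (running
    off the template), GC bounds, or the homopolymer rule are dropped; a
    ``PrimerSearchWarning`` with per-constraint rejection counts is issued
    when nothing survives.
    """
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not snps:
        raise ValueError("no SNPs supplied")
    if len(template) < params.len_min:
        raise ValueError("template shorter than len_min")

    rejections = {"out_of_template": 0, "gc": 0, "homopolymer": 0}
    out: list[PrimerCandidate] = []
    for snp in sorted(snps, key=lambda s: s.query_pos):
        for length in range(params.len_min, params.len_max + 1):
            if strand == "+":
                start, end = snp.query_pos + 1 - length, snp.query_pos + 1
            else:
                start, end = snp.query_pos, snp.query_pos + length
            if start < 0 or end > len(template):
                rejections["out_of_template"] += 1
                continue
            window = template.seq[start:end]
            seq = window if strand == "+" else reverse_complement(window)
            gc = gc_content(seq)
            if not params.gc_min <= gc <= params.gc_max:
                rejections["gc"] += 1
                continue
            if has_homopolymer(seq, params.max_homopolymer):
                rejections["homopolymer"] += 1
                continue
            covered = tuple(
                s for s in snps if start <= s.query_pos < end and s.query_pos == snp.query_pos
            )
            out.append(
                PrimerCandidate(
                    seq=seq,
                    strand=strand,
                    template_start=start,
                    template_end=end,
                    gc_percent=gc,
                    anchored_snps=covered,
                    terminal_base=seq[-1],
                )
            )
    if not out:
        warnings.warn(
            PrimerSearchWarning(
                f"no {strand}-strand primer survives the constraints "
                f"(rejections: {rejections})",
                rejections,
            )
        )
    return out


def _interior_snp_count(
    forward: PrimerCandidate, reverse: PrimerCandidate, snps: Sequence[SNPSite]
) -> int:
    """SNPs strictly between the two primer 3' ends on the plus strand."""
    lo = forward.template_end - 1  # forward 3' base
    hi = reverse.template_start  # reverse 3' base
    return sum(1 for s in snps if lo < s.query_pos < hi)


def assemble_pairs(
    forwards: Sequence[PrimerCandidate],
    reverses: Sequence[PrimerCandidate],
    params: DesignParams = DesignParams(),
    snps: Sequence[SNPSite] = (),
) -> list[PrimerPair]:
    """Assemble all valid forward x reverse combinations.

    A pair is valid when the amplicon (reverse.template_end -
    forward.template_start, including both primers) lies within the bounds,
    the primers do not overlap, and at least one further SNP lies strictly
    between the 3' ends.  If no pair fits the standard bounds and extension
    is allowed, the upper bound is relaxed to ``extension_cap``.  Pairs are
    sorted by closeness of the amplicon to the mid-range, then forward
    start.
    """
    if not forwards or not reverses:
        raise ValueError("need at least one forward and one reverse candidate")

    def collect(amplicon_max: int) -> list[PrimerPair]:
        pairs = []
        for fwd in forwards:
            for rev in reverses:
                if rev.template_end <= fwd.template_start:
                    continue
                amplicon = rev.template_end - fwd.template_start
                if amplicon < len(fwd) + len(rev):
                    continue  # 3' ends overlap
                if not params.amplicon_min <= amplicon <= amplicon_max:
                    continue
                interior = _interior_snp_count(fwd, rev, snps)
                if interior < 1:
                    continue
                pairs.append(
                    PrimerPair(
                        forward=fwd,
                        reverse=rev,
                        amplicon_len=amplicon,
                        interior_snp_count=interior,
                    )
                )
        return pairs

    pairs = collect(params.amplicon_max)
    if not pairs and params.allow_amplicon_extension:
        pairs = collect(params.extension_cap)
    midpoint = (params.amplicon_min + params.amplicon_max) / 2
    pairs.sort(
        key=lambda p: (abs(p.amplicon_len - midpoint), p.forward.template_start)
    )
    return pairs


def _select_duo(candidates: Sequence[PrimerCandidate], prefer_gc: bool):
    """Pick the two 'next to each other' candidates.

    Among all unordered pairs of distinct candidates, prefer pairs where
    both (then one) 3' terminal bases are G/C (soft preference), then the
    smallest start distance, then leftmost, then shortest.  With a single
    candidate, return it alone.
    """
    if len(candidates) <= 2:
        return list(candidates)

    def gc_rank(c: PrimerCandidate) -> int:
        return 0 if c.terminal_base in "GC" else 1

    best = None
    best_key = None
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            key = (
                (gc_rank(a) + gc_rank(b)) if prefer_gc else 0,
                abs(a.template_start - b.template_start),
                min(a.template_start, b.template_start),
                len(a) + len(b),
                a.seq,
                b.seq,
            )
            if best_key is None or key < best_key:
                best_key = key
                best = [a, b]
    assert best is not None
    best.sort(key=lambda c: (c.template_start, len(c)))
    return best


def design_assay(
    gene: SeqRecord,
    homolog_set: HomologSet,
    params: DesignParams = DesignParams(),
) -> list[PrimerPair]:
    """Design up to four labeled SNP-anchored primer pairs for a gene.

    Calls SNPs against the rank-1 homolog, enumerates anchored candidates
    on both strands, selects two adjacent forwards and two adjacent
    reverses (soft preference for a terminal G/C), and assembles all
    combinations.  Reverses are drawn from the subset able to form an
    in-bounds amplicon with a chosen forward, falling back to the global
    choice when that subset is too small.  Deterministic given inputs.
    """
    _, _, alignment = homolog_set.best()
    snps = call_snps(alignment)
    if not snps:
        raise ValueError(
            f"gene {gene.id!r} indistinguishable from nearest homolog (zero SNPs)"
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PrimerSearchWarning)
        forwards = enumerate_anchored_primers(gene, snps, params, strand="+")
        reverses = enumerate_anchored_primers(gene, snps, params, strand="-")
    if not forwards or not reverses:
        return []

    cap = (
        params.extension_cap
        if params.allow_amplicon_extension
        else params.amplicon_max
    )

    def compatible(fwd: PrimerCandidate, rev: PrimerCandidate) -> bool:
        amplicon = rev.template_end - fwd.template_start
        return (
            amplicon >= len(fwd) + len(rev)
            and params.amplicon_min <= amplicon <= cap
            and _interior_snp_count(fwd, rev, snps) >= 1
        )

    # restrict each strand's pool to candidates that can form a pair at all
    fwd_pool = [f for f in forwards if any(compatible(f, r) for r in reverses)]
    if not fwd_pool:
        warnings.warn(
            PrimerSearchWarning(
                f"gene {gene.id!r}: no forward/reverse combination yields a "
                "valid amplicon", {"no_valid_amplicon": 1},
            )
        )
        return []
    fwd_duo = _select_duo(fwd_pool, params.prefer_terminal_gc)

    rev_pool = [r for r in reverses if any(compatible(f, r) for f in fwd_duo)]
    rev_duo = _select_duo(rev_pool, params.prefer_terminal_gc)

    pairs = assemble_pairs(fwd_duo, rev_duo, params, snps)
    fwd_label = {id(c): f"F{i + 1}" for i, c in enumerate(fwd_duo)}
    rev_label = {id(c): f"R{i + 1}" for i, c in enumerate(rev_duo)}
    labeled = [
        PrimerPair(
            forward=p.forward,
            reverse=p.reverse,
            amplicon_len=p.amplicon_len,
            interior_snp_count=p.interior_snp_count,
            label=f"{fwd_label[id(p.forward)]}/{rev_label[id(p.reverse)]}",
        )
        for p in pairs
    ]
    return labeled
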