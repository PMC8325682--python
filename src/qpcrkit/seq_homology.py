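"""Homolog discovery and SNP calling for sequence-specific assay design.

Gene families in plant genomes are frequently multi-copy, and homologous
copies can be nearly identical at the nucleotide level.  The only positions
that discriminate a gene from its closest homolog are single-nucleotide
polymorphisms (SNPs), so primer design for copy-specific qPCR starts by
ranking a gene's homologs by global alignment identity and calling the SNP
columns against the most similar one.

This module also hosts the digital pre-screen of candidate reference genes
from an expression matrix (TPM), which filters for moderately, uniformly
expressed transcripts before any wet-lab work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "SeqRecord",
    "HomologSet",
    "SNPSite",
    "read_fasta",
    "rank_homologs",
    "call_snps",
    "prescreen_candidates",
    "write_snp_report",
]

logger = logging.getLogger(__name__)

_DNA_CHARS = set("ACGTN")
_PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")
GAP = "-"


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide or amino-acid sequence.

    ``alphabet`` is ``"dna"`` (A/C/G/T/N) or ``"protein"`` (IUPAC one-letter
    codes).  Sequences are stored uppercase; validation happens at
    construction.
    """

    id: str
    seq: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.alphabet == "dna":
            allowed = _DNA_CHARS
        elif self.alphabet == "protein":
            allowed = _PROTEIN_CHARS
        else:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SNPSite:
    """A discriminating alignment column mapped back to query coordinates.

    ``column`` indexes the gapped alignment; ``query_pos`` the ungapped
    query.  Both are 0-based; reports print 1-based coordinates.
    """

    column: int
    query_pos: int
    query_base: str
    homolog_base: str

    def __post_init__(self) -> None:
        if self.query_base == self.homolog_base:
            raise ValueError("SNP bases must differ")
        if GAP in (self.query_base, self.homolog_base):
            raise ValueError("SNP bases must be non-gap")


@dataclass
class HomologSet:
    """A query and its homologs ordered by decreasing alignment identity."""

    query: SeqRecord
    #: list of (record, identity fraction, (gapped query, gapped homolog))
    homologs: list[tuple[SeqRecord, float, tuple[str, str]]] = field(
        default_factory=list
    )

    def best(self) -> tuple[SeqRecord, float, tuple[str, str]]:
        """The most similar homolog (rank 1)."""
        if not self.homologs:
            raise ValueError(f"no homologs for {self.query.id!r}")
        return self.homologs[0]

    def __len__(self) -> int:
        return len(self.homologs)


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SeqRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Raises ``ValueError`` on an empty file or duplicate ids.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), alphabet=alphabet))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _make_aligner(alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "dna":
        # documented scheme: match +1, mismatch -1, gap -2 (linear)
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
    return aligner


def _align_pair(
    query: SeqRecord, candidate: SeqRecord, aligner: Align.PairwiseAligner
) -> tuple[float, tuple[str, str]]:
    """Globally align one pair; identity = matches / alignment columns."""
    alignment = aligner.align(query.seq, candidate.seq)[0]
    gapped_q, gapped_c = alignment[0], alignment[1]
    matches = sum(
        1 for a, b in zip(gapped_q, gapped_c) if a == b and a != GAP
    )
    identity = matches / len(gapped_q)
    return identity, (gapped_q, gapped_c)


def rank_homologs(
    query: SeqRecord,
    candidates: Sequence[SeqRecord],
    min_identity: float = 0.5,
) -> HomologSet:
    """Rank candidate homologs of ``query`` by global-alignment identity.

    Identity is matches over total alignment columns (gap columns count as
    mismatch), so it is a conservative fraction in [0, 1].  Candidates below
    ``min_identity`` are dropped ("lacked sequence homology").  Ties are
    broken by candidate id ascending; an empty candidate list yields an
    empty (valid) HomologSet.
    """
    for cand in candidates:
        if cand.alphabet != query.alphabet:
            raise ValueError(
                f"candidate {cand.id!r} alphabet {cand.alphabet!r} does not "
                f"match query alphabet {query.alphabet!r}"
            )
    aligner = _make_aligner(query.alphabet)
    scored = []
    for cand in candidates:
        identity, gapped = _align_pair(query, cand, aligner)
        if identity >= min_identity:
            scored.append((cand, identity, gapped))
    scored.sort(key=lambda item: (-item[1], item[0].id))
    return HomologSet(query=query, homologs=scored)


def call_snps(alignment: tuple[str, str]) -> list[SNPSite]:
    """Call SNP columns from a gapped pairwise alignment.

    A SNP is a column where both characters are non-gap and differ; columns
    with a gap on either side are indels, not SNPs, and are skipped.
    ``query_pos`` counts non-gap query characters before the column.
    """
    gapped_q, gapped_h = alignment
    if len(gapped_q) != len(gapped_h):
        raise ValueError(
            f"gapped strings differ in length ({len(gapped_q)} vs {len(gapped_h)})"
        )
    sites: list[SNPSite] = []
    query_pos = 0
    for col, (q, h) in enumerate(zip(gapped_q, gapped_h)):
        if q != GAP and h != GAP and q != h:
            sites.append(
                SNPSite(column=col, query_pos=query_pos, query_base=q, homolog_base=h)
            )
        if q != GAP:
            query_pos += 1
    return sites


def prescreen_candidates(
    expr: pd.DataFrame,
    min_tpm: float = 200.0,
    max_mean: float = 2000.0,
    max_cv: float = 0.35,
) -> list[str]:
    """Digitally pre-screen reference-gene candidates from a TPM matrix.

    ``expr`` is genes (rows) x samples (columns).  A gene is kept when its
    minimum over samples is >= ``min_tpm``, its mean is < ``max_mean``, and
    its coefficient of variation (sample SD / mean) is < ``max_cv``.  Input
    row order is preserved; all-zero rows have an undefined CV and are
    excluded with a log message.
    """
    if expr.empty:
        raise ValueError("expression matrix is empty")
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    kept: list[str] = []
    for gene, row in expr.iterrows():
        values = row.astype(float)
        mean = values.mean()
        if mean == 0.0:
            logger.warning("gene %s: all-zero expression, CV undefined; excluded", gene)
            continue
        cv = values.std(ddof=1) / mean
        if values.min() >= min_tpm and mean < max_mean and cv < max_cv:
            kept.append(gene)
    return kept


def write_snp_report(
    path: str | Path,
    gene_id: str,
    homolog_id: str,
    identity: float,
    snps: Iterable[SNPSite],
) -> None:
    """Write the SNP report CSV (1-based query coordinates)."""
    rows = [
        {
            "gene_id": gene_id,
            "homolog_id": homolog_id,
            "identity": identity,
            "query_pos_1based": s.query_pos + 1,
            "query_base": s.query_base,
            "homolog_base": s.homolog_base,
        }
        for s in snps
    ]
    pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "homolog_id",
            "identity",
            "query_pos_1based",
            "query_base",
            "homolog_base",
        ],
    ).to_csv(path, index=False)
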