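"""Synthetic fixtures: Ct tables with planted stability structure and
homologous gene families with planted SNPs.

The study's raw Ct data and primer sequences are not published, so every
downstream module is exercised on simulated data whose ground truth is
known by construction.  The Ct generator writes the additive model

    Ct_gikt = baseline_g + group_effect_gk + dilution_term + N(0, noise_sd)
              + N(0, tech_rep_sd)

where the dilution term adds log_base(factor / first_factor) cycles when a
serial dilution is attached (one extra cycle per twofold dilution at base
2, so a noise-free series fits to exactly 100% efficiency).  Noise is
Gaussian on the Ct (log-quantity) scale; one seeded generator is consumed
in documented order (genes outer, samples middle, tech reps inner), so a
spec plus seed reproduces a byte-identical table.

The family generator draws a random base sequence at a target GC and
derives homologous copies by substituting a fixed set of SNP positions
(no indels), kept >= 25 nt from either terminus so anchored primer windows
always fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curve_optimization import CT_COLUMNS, DilutionSeries
from .seq_homology import SeqRecord

__all__ = [
    "GeneSpec",
    "CtSimSpec",
    "FamilySimSpec",
    "simulate_ct",
    "simulate_gene_family",
    "write_family_fasta",
]

SNP_TERMINAL_MARGIN = 25


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline Ct, efficiency base, group shifts, noise."""

    name: str
    baseline_ct: float = 25.0
    efficiency_base: float = 2.0
    group_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 10.0 < self.baseline_ct < 38.0:
            raise ValueError("baseline_ct must lie in (10, 38)")


@dataclass(frozen=True)
class CtSimSpec:
    """Recipe for a synthetic long-format Ct table."""

    genes: tuple[GeneSpec, ...]
    groups: dict[str, int] = field(default_factory=lambda: {"g1": 6})
    tech_reps: int = 3
    tech_rep_sd: float = 0.1
    dilution: DilutionSeries | None = None
    anneal_temp_C: float = 60.6
    primer_conc: str = "350"
    seed: int = 0


@dataclass(frozen=True)
class FamilySimSpec:
    """Recipe for a synthetic homologous gene family with planted SNPs."""

    length: int = 600
    n_copies: int = 2
    n_snps: int = 6
    gc_target: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps >= self.length:
            raise ValueError("n_snps must be < length")
        usable = self.length - 2 * SNP_TERMINAL_MARGIN
        if self.n_snps > max(usable, 0):
            raise ValueError(
                f"cannot place {self.n_snps} SNPs >= {SNP_TERMINAL_MARGIN} nt "
                f"from the termini of a {self.length} nt sequence"
            )


def simulate_ct(spec: CtSimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a long-format Ct table plus a ground-truth record.

    The ground truth carries each gene's noise SD and group effects — the
    inputs that determine the true stability ordering — and, when a
    dilution series is attached, the exact dilution term per level.
    """
    rng = np.random.default_rng(spec.seed)
    dilution_levels: list[tuple[str, float | None]]
    rows = []
    for gene in spec.genes:
        if spec.dilution is not None:
            base_factor = spec.dilution.dilution_factors[0]
            dilution_levels = [
                (
                    label,
                    np.log(factor / base_factor)
                    / np.log(gene.efficiency_base),
                )
                for label, factor in zip(
                    spec.dilution.labels, spec.dilution.dilution_factors
                )
            ]
        else:
            dilution_levels = [("", 0.0)]
        for group, n_samples in spec.groups.items():
            effect = gene.group_effects.get(group, 0.0)
            for i in range(1, n_samples + 1):
                bio_noise = rng.normal(0.0, gene.noise_sd) if gene.noise_sd else 0.0
                for dil_label, dil_term in dilution_levels:
                    mean_ct = gene.baseline_ct + effect + dil_term + bio_noise
                    for t in range(1, spec.tech_reps + 1):
                        jitter = (
                            rng.normal(0.0, spec.tech_rep_sd)
                            if spec.tech_rep_sd
                            else 0.0
                        )
                        rows.append(
                            {
                                "sample_id": f"{group}_s{i}",
                                "group": group,
                                "gene": gene.name,
                                "pair": "F1/R1",
                                "anneal_temp_C": spec.anneal_temp_C,
                                "primer_conc": spec.primer_conc,
                                "dilution": dil_label,
                                "bio_rep": 1,
                                "tech_rep": t,
                                "ct": mean_ct + jitter,
                            }
                        )
    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    truth = {
        "genes": {
            g.name: {
                "baseline_ct": g.baseline_ct,
                "efficiency_base": g.efficiency_base,
                "group_effects": dict(g.group_effects),
                "noise_sd": g.noise_sd,
            }
            for g in spec.genes
        },
        "seed": spec.seed,
    }
    return table, truth


_BASES = np.array(list("ACGT"))


def simulate_gene_family(
    spec: FamilySimSpec,
) -> tuple[list[SeqRecord], dict[str, list[tuple[int, str, str]]]]:
    """Generate a query gene plus homologous copies with planted SNPs.

    All copies substitute the same ``n_snps`` positions (each copy drawing
    its own alternate base), sampled without replacement at least 25 nt
    from either terminus.  Returns the records (query first) and a map
    copy id -> [(position, query base, copy base), ...].
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array(
        [
            (1 - spec.gc_target) / 2,
            spec.gc_target / 2,
            spec.gc_target / 2,
            (1 - spec.gc_target) / 2,
        ]
    )
    query_arr = rng.choice(_BASES, size=spec.length, p=p)
    positions = np.sort(
        rng.choice(
            np.arange(SNP_TERMINAL_MARGIN, spec.length - SNP_TERMINAL_MARGIN),
            size=spec.n_snps,
            replace=False,
        )
    )
    records = [SeqRecord(id="query", seq="".join(query_arr))]
    truth: dict[str, list[tuple[int, str, str]]] = {}
    for c in range(1, spec.n_copies + 1):
        copy_arr = query_arr.copy()
        planted = []
        for pos in positions:
            ref = copy_arr[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            copy_arr[pos] = alt
            planted.append((int(pos), str(ref), str(alt)))
        copy_id = f"copy{c}"
        records.append(SeqRecord(id=copy_id, seq="".join(copy_arr)))
        truth[copy_id] = planted
    return records, truth


def write_family_fasta(
    path: str | Path,
    records: list[SeqRecord],
    truth_path: str | Path | None = None,
    truth: dict | None = None,
) -> None:
    """Write a simulated family as FASTA (and optionally its SNP truth CSV)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")
    if truth_path is not None and truth is not None:
        rows = [
            {
                "copy_id": copy_id,
                "position_1based": pos + 1,
                "query_base": ref,
                "copy_base": alt,
            }
            for copy_id, planted in truth.items()
            for pos, ref, alt in planted
        ]
        pd.DataFrame(rows).to_csv(truth_path, index=False)
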