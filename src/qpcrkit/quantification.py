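"""Relative quantification: 2^-ddCt and the efficiency-calibrated ratio.

Ct is a log2-scale proxy for starting template: under perfect doubling, a
twofold expression difference is one cycle.  The 2^-ddCt estimator
normalizes a target gene to one or more reference genes (their Ct combined
as a geometric mean, generalizing the two-gene square-root-of-product
rule) and to a calibrator sample:

    dCt_s   = Ct_target(s) - Ct_ref(s)
    ddCt    = dCt_s - dCt_calibrator
    fold    = 2 ** (-ddCt)

The efficiency-calibrated (Pfaffl) form replaces the shared base 2 with
per-gene amplification bases b = 1 + E%/100:

    fold = b_target ** dCt_target / b_ref ** dCt_ref

with dCt = Ct_calibrator - Ct_sample per gene.  The two coincide exactly
when every base is 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .curve_optimization import mean_tech_reps

__all__ = [
    "QuantRequest",
    "ExpressionResult",
    "reference_ct",
    "ddct_fold_change",
    "efficiency_calibrated_ratio",
    "quantify",
]


@dataclass(frozen=True)
class QuantRequest:
    """What to quantify: target vs references, relative to a calibrator."""

    target_gene: str
    reference_genes: tuple[str, ...]
    calibrator_sample: str
    #: per-gene fold-amplification base (1 + E/100); genes default to 2.0
    efficiencies: dict[str, float] = field(default_factory=dict)
    method: str = "ddct"

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise ValueError("at least one reference gene is required")
        for gene, base in self.efficiencies.items():
            if not 1.0 < base <= 2.5:
                raise ValueError(
                    f"gene {gene!r}: amplification base {base} outside (1, 2.5]"
                )
        if self.method not in ("ddct", "efficiency_calibrated"):
            raise ValueError(f"unknown method {self.method!r}")

    def base(self, gene: str) -> float:
        return self.efficiencies.get(gene, 2.0)


@dataclass(frozen=True)
class ExpressionResult:
    sample_id: str
    fold_change: float
    method: str
    dct_target: float
    dct_reference: float
    sem: float | None = None


def reference_ct(cts: Sequence[float]) -> float:
    """Geometric mean of reference-gene Cts for one sample.

    Generalizes the two-gene rule (product, then square root) to n genes.
    Any ND (NaN) reference propagates ND.
    """
    if not len(cts):
        raise ValueError("no reference Cts")
    arr = np.asarray(cts, dtype=float)
    if np.isnan(arr).any():
        return float("nan")
    if (arr <= 0).any():
        raise ValueError("Ct values must be positive")
    return float(np.exp(np.mean(np.log(arr))))


def ddct_fold_change(
    ct_target_s: float,
    ct_ref_s: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """2^-ddCt fold change of a sample relative to the calibrator."""
    dct_s = ct_target_s - ct_ref_s
    dct_cal = ct_target_cal - ct_ref_cal
    return 2.0 ** (-(dct_s - dct_cal))


def efficiency_calibrated_ratio(
    base_target: float,
    base_ref: float,
    dct_target: float,
    dct_ref: float,
) -> float:
    """Efficiency-calibrated (Pfaffl) expression ratio.

    ``dct_*`` is Ct(calibrator) - Ct(sample) per gene; bases are per-gene
    fold amplification per cycle (1 + E/100), in (1, 2.5].
    """
    for base in (base_target, base_ref):
        if not 1.0 < base <= 2.5:
            raise ValueError(f"amplification base {base} outside (1, 2.5]")
    return base_target**dct_target / base_ref**dct_ref


def _sample_gene_ct(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tech-rep-collapsed table to (sample, bio_rep) x gene Ct."""
    return collapsed.pivot_table(
        index=["sample_id", "bio_rep"],
        columns="gene",
        values="ct",
        aggfunc="mean",
        dropna=False,
    )


def quantify(table: pd.DataFrame, request: QuantRequest) -> list[ExpressionResult]:
    """Quantify relative expression per sample from a long-format Ct table.

    Technical replicates are collapsed first.  Each biological replicate is
    quantified independently against the calibrator sample's mean dCt;
    per-sample results report the fold change computed from the sample's
    mean dCt (so the calibrator's ddCt fold is exactly 1) with the standard
    error over the replicate-level folds.
    """
    collapsed = mean_tech_reps(table)
    wide = _sample_gene_ct(collapsed)
    genes_needed = (request.target_gene, *request.reference_genes)
    for gene in genes_needed:
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} not present in Ct table")

    ref = wide[list(request.reference_genes)].apply(
        lambda row: reference_ct(row.values), axis=1
    )
    per_rep = pd.DataFrame(
        {
            "sample_id": wide.index.get_level_values("sample_id"),
            "ct_target": wide[request.target_gene].values,
            "ct_ref": ref.values,
        }
    )
    per_rep["dct"] = per_rep["ct_target"] - per_rep["ct_ref"]

    cal = per_rep[per_rep["sample_id"] == request.calibrator_sample]
    if cal.empty:
        raise ValueError(
            f"calibrator sample {request.calibrator_sample!r} not in table"
        )
    cal_target = float(cal["ct_target"].mean())
    cal_ref = float(cal["ct_ref"].mean())
    dct_cal = cal_target - cal_ref

    def fold_from(ct_target: float, ct_ref: float) -> float:
        if request.method == "ddct":
            return ddct_fold_change(ct_target, ct_ref, cal_target, cal_ref)
        return efficiency_calibrated_ratio(
            request.base(request.target_gene),
            # a multi-gene reference uses the geometric-mean base
            reference_ct([request.base(g) for g in request.reference_genes]),
            cal_target - ct_target,
            cal_ref - ct_ref,
        )

    results: list[ExpressionResult] = []
    for sample, sub in per_rep.groupby("sample_id", sort=False):
        mean_target = float(sub["ct_target"].mean())
        mean_ref = float(sub["ct_ref"].mean())
        fold = fold_from(mean_target, mean_ref)
        rep_folds = [
            fold_from(float(r.ct_target), float(r.ct_ref))
            for r in sub.itertuples()
            if not (math.isnan(r.ct_target) or math.isnan(r.ct_ref))
        ]
        sem = (
            float(np.std(rep_folds, ddof=1) / math.sqrt(len(rep_folds)))
            if len(rep_folds) > 1
            else None
        )
        results.append(
            ExpressionResult(
                sample_id=str(sample),
                fold_change=fold,
                method=request.method,
                dct_target=mean_target - mean_ref,
                dct_reference=dct_cal,
                sem=sem,
            )
        )
    return results
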