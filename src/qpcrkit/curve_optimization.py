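"""Standard-curve fitting, condition selection, and efficiency acceptance.

A qPCR assay is validated on a serial dilution of template: the threshold
cycle Ct is regressed on log10 input mass, and the amplification efficiency
follows from the slope A as::

    E(%) = (10 ** (-1 / A) - 1) * 100

Perfect doubling per cycle gives A = -1/log10(2) = -3.3219 and E = 100%.
An assay is accepted when R^2 >= ``r2_min`` (default 0.99) and E is within
``tol`` (default 5) percentage points of 100.  Because the exponential
phase may not span the whole dilution range, up to two points may be
trimmed from either end of the series (never the interior) to find the
best consecutive subrange that passes.

Condition selection (annealing temperature, then primer concentration) is
by lowest mean Ct, sequentially, mirroring the stepwise protocol.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CT_COLUMNS",
    "DilutionSeries",
    "StandardCurveFit",
    "read_ct_table",
    "validate_ct_table",
    "mean_tech_reps",
    "select_lowest_ct_condition",
    "fit_standard_curve",
    "search_best_subrange",
    "select_best_pair",
    "write_fit_report",
]

logger = logging.getLogger(__name__)

#: canonical long-format Ct table columns; ``ct`` empty/NaN encodes ND
CT_COLUMNS = [
    "sample_id",
    "group",
    "gene",
    "pair",
    "anneal_temp_C",
    "primer_conc",
    "dilution",
    "bio_rep",
    "tech_rep",
    "ct",
]

_KEY_COLUMNS = CT_COLUMNS[:-1]


@dataclass(frozen=True)
class DilutionSeries:
    """A stepwise serial dilution of template.

    ``stock_conc`` in ng/ul, strictly increasing ``dilution_factors``
    (e.g. 10, 20, 40, 80, 160), and ``volume_per_reaction`` in ul.  The
    fitted x-axis is log10(ng per reaction).
    """

    stock_conc: float = 50.0
    dilution_factors: tuple[float, ...] = (10.0, 20.0, 40.0, 80.0, 160.0)
    volume_per_reaction: float = 1.0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.dilution_factors):
            raise ValueError("dilution factors must be positive")
        if list(self.dilution_factors) != sorted(set(self.dilution_factors)):
            raise ValueError("dilution factors must be strictly increasing")

    @property
    def concentrations(self) -> list[float]:
        """Template concentration at each dilution, ng/ul."""
        return [self.stock_conc / f for f in self.dilution_factors]

    @property
    def log_inputs(self) -> list[float]:
        """log10(ng per reaction) at each dilution."""
        return [
            math.log10(c * self.volume_per_reaction) for c in self.concentrations
        ]

    @property
    def labels(self) -> list[str]:
        return [f"1:{f:g}" for f in self.dilution_factors]


@dataclass
class StandardCurveFit:
    """Least-squares line Ct = A*log_input + B with acceptance verdict."""

    A: float
    B: float
    r2: float
    efficiency_pct: float
    points_used: tuple[int, ...]
    passes: bool
    n_points: int = 0
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.n_points:
            self.n_points = len(self.points_used)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct CSV; empty ``ct`` fields become NaN (ND)."""
    table = pd.read_csv(path, dtype={"dilution": str, "primer_conc": str})
    validate_ct_table(table)
    return table


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = table["ct"].dropna()
    if (ct <= 0).any():
        raise ValueError("Ct values must be positive (empty field = ND)")
    dup = table.duplicated(subset=_KEY_COLUMNS)
    if dup.any():
        first = table.loc[dup.idxmax(), _KEY_COLUMNS].to_dict()
        raise ValueError(f"duplicate Ct observation key: {first}")


def mean_tech_reps(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to their arithmetic mean.

    ND (NaN) values never enter the mean; a key whose tech reps are all ND
    stays ND.  ND counts per collapsed key are logged.
    """
    keys = [c for c in _KEY_COLUMNS if c != "tech_rep"]
    n_nd = int(table["ct"].isna().sum())
    if n_nd:
        logger.info("mean_tech_reps: %d ND technical replicates excluded", n_nd)
    out = (
        table.groupby(keys, sort=False, dropna=False)["ct"]
        .mean()  # skipna: all-ND groups yield NaN
        .reset_index()
    )
    return out


def _condition_sort_key(level) -> tuple:
    """Order condition levels numerically when possible, else as strings."""
    try:
        return (0, float(level), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(level))


def select_lowest_ct_condition(
    table: pd.DataFrame, vary: str
) -> tuple[dict[str, object], pd.DataFrame]:
    """Pick, per primer pair, the level of ``vary`` with the lowest mean Ct.

    ``vary`` is ``"anneal_temp_C"`` or ``"primer_conc"``.  Ties go to the
    lower level (numeric when the label parses as a number).  Levels with
    only ND data are excluded and logged.  Returns (per-pair optimum, the
    full per-level audit table).
    """
    if vary not in ("anneal_temp_C", "primer_conc"):
        raise ValueError(f"cannot vary {vary!r}")
    collapsed = mean_tech_reps(table)
    audit = (
        collapsed.groupby(["pair", vary], sort=False)["ct"].mean().reset_index()
    )
    best: dict[str, object] = {}
    for pair, sub in audit.groupby("pair", sort=False):
        usable = sub.dropna(subset=["ct"])
        dropped = set(sub[vary]) - set(usable[vary])
        if dropped:
            logger.warning(
                "pair %s: %s levels %s had only ND data; excluded",
                pair, vary, sorted(dropped, key=_condition_sort_key),
            )
        if usable.empty:
            continue
        min_ct = usable["ct"].min()
        tied = usable.loc[usable["ct"] == min_ct, vary].tolist()
        best[pair] = sorted(tied, key=_condition_sort_key)[0]
    return best, audit


def fit_standard_curve(
    points: list[tuple[float, float]],
    r2_min: float = 0.99,
    tol: float = 5.0,
    points_used: tuple[int, ...] | None = None,
) -> StandardCurveFit:
    """Fit Ct against log10 input and compute the amplification efficiency.

    Requires >= 3 points with distinct log_input.  ``r2`` is the squared
    Pearson correlation.  A non-negative slope cannot represent
    amplification; the fit is returned with ``passes=False`` and a warning
    rather than raising.
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points, got {len(points)}")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.isnan(y).any():
        raise ValueError("ND mean Ct in standard-curve points")
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct log_input values")
    res = stats.linregress(x, y)
    A, B = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue) ** 2
    if points_used is None:
        points_used = tuple(range(len(points)))
    if A >= 0:
        return StandardCurveFit(
            A=A, B=B, r2=r2, efficiency_pct=float("nan"),
            points_used=points_used, passes=False,
            warning="non-amplifying slope (A >= 0)",
        )
    try:
        efficiency = (10.0 ** (-1.0 / A) - 1.0) * 100.0
    except OverflowError:  # slope indistinguishable from zero
        efficiency = float("inf")
    passes = r2 >= r2_min and abs(efficiency - 100.0) <= tol
    return StandardCurveFit(
        A=A, B=B, r2=r2, efficiency_pct=efficiency,
        points_used=points_used, passes=passes,
    )


def search_best_subrange(
    points: list[tuple[float, float]],
    r2_min: float = 0.99,
    tol: float = 5.0,
    max_trim: int = 2,
    min_points: int = 3,
) -> StandardCurveFit:
    """Find the best consecutive dilution subrange passing the acceptance.

    ``points`` are ordered by log_input descending (highest concentration
    first).  Candidate subranges trim 0..``max_trim`` points from the high
    end and/or the low end, keeping >= ``min_points``; only series ends may
    be trimmed, never interior points.  Among passing subranges prefer the
    most points, then the highest r2, then the smallest |E - 100|.  When no
    subrange passes, the full-range fit is returned with ``passes=False``.
    """
    n = len(points)
    best: StandardCurveFit | None = None
    best_key = None
    for lo_trim, hi_trim in itertools.product(range(max_trim + 1), repeat=2):
        if n - lo_trim - hi_trim < min_points:
            continue
        idx = tuple(range(lo_trim, n - hi_trim))
        sub = [points[i] for i in idx]
        if any(math.isnan(ct) for _, ct in sub):
            continue  # a subrange containing an ND mean point is ineligible
        fit = fit_standard_curve(sub, r2_min=r2_min, tol=tol, points_used=idx)
        if not fit.passes:
            continue
        key = (-fit.n_points, -fit.r2, abs(fit.efficiency_pct - 100.0))
        if best_key is None or key < best_key:
            best_key, best = key, fit
    if best is not None:
        return best
    if any(math.isnan(ct) for _, ct in points):
        # full range ineligible (ND point): fall back to the longest
        # eligible window, preferring the least-trimmed one
        for lo_trim, hi_trim in sorted(
            itertools.product(range(max_trim + 1), repeat=2),
            key=lambda t: (t[0] + t[1], t[1]),
        ):
            if n - lo_trim - hi_trim < min_points:
                continue
            idx = tuple(range(lo_trim, n - hi_trim))
            sub = [points[i] for i in idx]
            if any(math.isnan(ct) for _, ct in sub):
                continue
            fit = fit_standard_curve(sub, r2_min=r2_min, tol=tol, points_used=idx)
            fit.passes = False
            return fit
        raise ValueError("no ND-free subrange of >= 3 points")
    full = fit_standard_curve(points, r2_min=r2_min, tol=tol)
    full.passes = False
    return full


def select_best_pair(fits: dict[str, StandardCurveFit]) -> tuple[str, bool]:
    """Choose the best primer pair for a gene from its per-pair fits.

    Among passing fits: highest r2, then smallest |E - 100|, then label
    order.  When no pair passes, the highest-r2 pair is chosen best-effort
    and the gene is flagged (validated=False).
    """
    if not fits:
        raise ValueError("no fits supplied")
    passing = {k: f for k, f in fits.items() if f.passes}
    pool, validated = (passing, True) if passing else (fits, False)
    if validated:
        label = min(
            pool,
            key=lambda k: (-pool[k].r2, abs(pool[k].efficiency_pct - 100.0), k),
        )
    else:
        label = min(pool, key=lambda k: (-pool[k].r2, k))
    return label, validated


def write_fit_report(
    path: str | Path, fits: dict[tuple[str, str], StandardCurveFit]
) -> None:
    """Write per-pair fit CSV keyed by (gene, pair)."""
    rows = [
        {
            "gene": gene,
            "pair": pair,
            "A": fit.A,
            "B": fit.B,
            "r2": fit.r2,
            "efficiency_pct": fit.efficiency_pct,
            "points_used": ";".join(map(str, fit.points_used)),
            "passes": fit.passes,
        }
        for (gene, pair), fit in fits.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
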