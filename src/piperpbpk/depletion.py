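"""Intrinsic clearance from microsomal substrate-depletion time courses.

The depletion assay follows the percentage of parent compound remaining
over an incubation with human liver microsomes.  Under first-order loss,
ln(% remaining) is linear in time; the (positive) decay slope k maps to an
intrinsic clearance via

    CLint (uL/min/mg protein) = 1000 * k / P

with P the microsomal protein concentration in mg/mL.  Condition-level
estimates (different protein and substrate concentrations, in-house and
literature) are pooled by unweighted arithmetic mean into the single model
input value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError


@dataclass(frozen=True)
class DepletionDataset:
    """One substrate-depletion time course at a single incubation condition.

    ``times`` in minutes (first element 0), ``remaining`` in percent of the
    zero-time substrate (first element 100), ``protein_conc`` in mg/mL.
    """

    times: tuple
    remaining: tuple
    protein_conc: float
    substrate_conc: Optional[float] = None  # uM, annotation only
    replicate_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.remaining, dtype=float)
        if t.size != r.size:
            raise InvalidInputError("times and remaining differ in length")
        if t.size < 3:
            raise InvalidInputError("need at least 3 time points")
        if t[0] != 0:
            raise InvalidInputError("first sampling time must be 0")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(r <= 0):
            raise InvalidInputError(
                "remaining percentages must be positive (log transform)")
        if self.protein_conc <= 0:
            raise InvalidInputError("protein_conc must be positive")


@dataclass(frozen=True)
class ClintEstimate:
    """Result of one condition-level depletion fit."""

    slope: float        # positive first-order decay rate, 1/min
    clint: float        # uL/min/mg protein
    r_squared: float
    condition: tuple    # (protein_conc mg/mL, substrate_conc uM)


def clint_from_slope(slope: float, protein_conc: float) -> float:
    """CLint = 1000 * slope / P (uL/min/mg protein == mL/min/g protein)."""
    if protein_conc <= 0:
        raise InvalidInputError("protein_conc must be positive")
    if slope < 0:
        raise InvalidInputError("slope must be a non-negative decay rate")
    return 1000.0 * slope / protein_conc


def average_replicates(datasets: Sequence[DepletionDataset]) -> DepletionDataset:
    """Average replicate incubations per time point before fitting.

    All replicates must share the sampling grid and condition.
    """
    if not datasets:
        raise InvalidInputError("no datasets given")
    first = datasets[0]
    for d in datasets[1:]:
        if d.times != first.times:
            raise InvalidInputError("replicates must share sampling times")
        if d.protein_conc != first.protein_conc:
            raise InvalidInputError("replicates must share protein_conc")
    mean_rem = tuple(np.mean([d.remaining for d in datasets], axis=0))
    return DepletionDataset(first.times, mean_rem, first.protein_conc,
                            first.substrate_conc, replicate_id="mean")


def fit_depletion_slope(dataset: DepletionDataset) -> ClintEstimate:
    """OLS fit of ln(% remaining) against incubation time.

    The fitted regression coefficient is negated so the reported slope is
    the positive first-order decay rate; a flat (or rising) time course
    yields slope 0.
    """
    t = np.asarray(dataset.times, dtype=float)
    y = np.log(np.asarray(dataset.remaining, dtype=float))
    fit = stats.linregress(t, y)
    slope = max(0.0, -fit.slope)
    r_squared = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return ClintEstimate(
        slope=slope,
        clint=clint_from_slope(slope, dataset.protein_conc),
        r_squared=r_squared,
        condition=(dataset.protein_conc, dataset.substrate_conc),
    )


def pool_clint(estimates: Iterable) -> float:
    """Unweighted arithmetic mean of condition-level CLint values.

    Accepts ClintEstimate records or bare numbers (literature values carry
    no fit metadata).
    """
    values = [e.clint if isinstance(e, ClintEstimate) else float(e)
              for e in estimates]
    if not values:
        raise InvalidInputError("cannot pool an empty list")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Delimited-text IO
#
# Format: '#'-prefixed metadata header lines (protein_conc_mg_ml,
# substrate_uM), then TSV columns time_min, remaining_pct, replicate.

def read_depletion_table(path: str | Path) -> list[DepletionDataset]:
    """Read one depletion table; returns one dataset per replicate label."""
    path = Path(path)
    meta = {}
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            meta[key.strip()] = value.strip()
        else:
            rows.append(line)
    if "protein_conc_mg_ml" not in meta:
        raise InvalidInputError(f"{path}: missing protein_conc_mg_ml header")
    df = pd.read_csv(pd.io.common.StringIO("\n".join(rows)), sep="\t")
    required = {"time_min", "remaining_pct", "replicate"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: need columns {sorted(required)}")
    protein = float(meta["protein_conc_mg_ml"])
    substrate = float(meta["substrate_uM"]) if "substrate_uM" in meta else None
    out = []
    for rep, grp in df.groupby("replicate", sort=False):
        grp = grp.sort_values("time_min")
        out.append(DepletionDataset(
            tuple(grp["time_min"]), tuple(grp["remaining_pct"]),
            protein, substrate, replicate_id=str(rep)))
    return out


def write_depletion_table(datasets: Sequence[DepletionDataset],
                          path: str | Path) -> None:
    first = datasets[0]
    lines = [f"# protein_conc_mg_ml = {first.protein_conc}"]
    if first.substrate_conc is not None:
        lines.append(f"# substrate_uM = {first.substrate_conc}")
    lines.append("time_min\tremaining_pct\treplicate")
    for d in datasets:
        for t, r in zip(d.times, d.remaining):
            lines.append(f"{t}\t{r}\t{d.replicate_id}")
    Path(path).write_text("\n".join(lines) + "\n")
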