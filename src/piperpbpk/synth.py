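"""Synthetic ground-truth data generators.

Every pipeline input can be generated with known truth so each stage is
testable end to end: microsomal depletion time courses (ln-linear decay
with proportional log-normal noise), clinical-like sparse "observed"
plasma profiles (simulated with perturbed parameters plus proportional
noise), and the bundled ten-victim fixture table.  All generators are
pure functions of (parameters, seed).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import ConcProfile, DoseSchedule, ModelOptions, build_model
from .errors import InvalidInputError
from .depletion import DepletionDataset
from .params import CompoundParams
from .physiology import DEFAULT_PHYSIOLOGY, Physiology

DEPLETION_TIMES = (0.0, 7.0, 17.0, 30.0, 60.0)       # min, assay design
CLINICAL_TIMES = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)  # h


def _lognormal_noise(rng, cv: float, n: int) -> np.ndarray:
    if cv < 0:
        raise InvalidInputError("noise_cv must be non-negative")
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(sigma * rng.standard_normal(n))


def gen_depletion(true_clint: float, protein_conc: float,
                  times: Sequence[float] = DEPLETION_TIMES,
                  noise_cv: float = 0.0, seed: int = 0,
                  substrate_conc: Optional[float] = None,
                  replicate_id: str = "synthetic") -> DepletionDataset:
    """Exponential depletion with known CLint and proportional noise.

    remaining% = 100 exp(-k t) with k = true_clint * P / 1000 (1/min);
    the zero-time anchor carries no noise.
    """
    if true_clint < 0:
        raise InvalidInputError("true_clint must be non-negative")
    t = np.asarray(times, dtype=float)
    k = true_clint * protein_conc / 1000.0
    remaining = 100.0 * np.exp(-k * t)
    rng = np.random.default_rng(seed)
    mult = _lognormal_noise(rng, noise_cv, t.size)
    mult[t == 0] = 1.0
    return DepletionDataset(tuple(t), tuple(remaining * mult), protein_conc,
                            substrate_conc, replicate_id=replicate_id)


def gen_observed_profile(compound: CompoundParams,
                         physiology: Physiology = DEFAULT_PHYSIOLOGY,
                         schedule: Optional[DoseSchedule] = None,
                         param_perturbation: Optional[Mapping[str, float]] = None,
                         noise_cv: float = 0.0, seed: int = 0,
                         sample_times: Sequence[float] = CLINICAL_TIMES,
                         options: ModelOptions = ModelOptions()) -> ConcProfile:
    """Clinical-like sparse noisy profile with known generating model.

    ``param_perturbation`` maps compound field names to multiplicative
    factors applied before simulation (the ground-truth misspecification);
    proportional log-normal noise is added at the sparse sampling times.
    """
    perturbed = compound
    if param_perturbation:
        updates = {}
        for name, factor in param_perturbation.items():
            value = getattr(compound, name)
            if value is None:
                raise InvalidInputError(f"cannot perturb unset field {name}")
            updates[name] = value * factor
        perturbed = compound.with_(**updates)
    model = build_model(perturbed, physiology, schedule, options)
    t_sample = np.asarray(sample_times, dtype=float)
    dense = model.simulate(float(t_sample.max()) + 1.0, output_step_h=0.05)
    conc = np.interp(t_sample, dense.time_h, dense.conc_ng_ml)
    rng = np.random.default_rng(seed)
    conc = conc * _lognormal_noise(rng, noise_cv, t_sample.size)
    return ConcProfile(t_sample, conc)


def victim_fixtures(path: str | Path | None = None) -> list[CompoundParams]:
    """The bundled, literature-annotated ten-victim parameter set."""
    if path is None:
        path = Path(__file__).parent / "data" / "victims.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.to_dict("records"):
        out.append(CompoundParams(
            name=row["name"], mw=row["mw"], dose_mg=row["dose_mg"],
            fu_plasma=row["fu_plasma"], bp_ratio=row["bp_ratio"],
            vss=row["vss"], ka=row["ka"],
            clint_u_liver=row["clint_u_liver"], fm_cyp3a4=row["fm_cyp3a4"],
            fu_gut=row["fu_gut"], qgut=row["qgut"],
            clint_gut=row["clint_gut"], renal_cl=row["renal_cl"],
            source_note=row["source_note"]))
    return out
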