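"""Seeded synthetic benchmark datasets: truths, spectra and noisy predictions.

Emulates the structure of a predictor-benchmark dataset — a set of molecules
with known proton shift lists, their "experimental" spectra, and shift lists
perturbed by Gaussian noise standing in for predictor error — so the whole
evaluation pipeline can be exercised without any external download.  No
chemistry is involved: shifts are sampled uniformly, because the evaluation
machinery only ever consumes shift lists and spectra.

Truth generation, prediction perturbation and spectral noise use three
independent RNG streams keyed off the same seed, so sweeps over the
perturbation scale share identical ground truths (paired comparisons).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simulator import SimulationParams, simulate_spectrum
from .spectra_io import (
    AssignmentTable,
    PredictionSet,
    ProtonGroup,
    Spectrum,
    normalize_total,
)

_TRUTH_STREAM = 0
_PRED_STREAM = 1
_NOISE_STREAM = 2


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for a synthetic benchmark dataset.

    Defaults mimic routine small-molecule 1H data: a handful of proton
    groups per molecule spread over 0.5-9.5 ppm, mostly 1-3 equivalent
    protons, about half the groups showing one resolvable coupling of
    2-12 Hz.
    """

    n_molecules: int = 100
    groups_range: tuple[int, int] = (2, 8)
    shift_range: tuple[float, float] = (0.5, 9.5)
    n_protons_choices: tuple[int, ...] = (1, 2, 3)
    n_protons_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    coupling_prob: float = 0.5
    j_range: tuple[float, float] = (2.0, 12.0)
    sigma_pred: float = 0.0
    sigma_exp_noise: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.sigma_pred < 0 or self.sigma_exp_noise < 0:
            raise ValueError("noise scales must be >= 0")
        if self.groups_range[0] > self.groups_range[1] or self.groups_range[0] < 1:
            raise ValueError("invalid groups_range")
        if self.shift_range[0] >= self.shift_range[1]:
            raise ValueError("invalid shift_range")
        if len(self.n_protons_choices) != len(self.n_protons_weights):
            raise ValueError("n_protons_choices and weights differ in length")


def generate_truth(cfg: SynthConfig) -> list[PredictionSet]:
    """Sample seeded ground-truth shift lists, one PredictionSet per molecule."""
    rng = np.random.default_rng([cfg.seed, _TRUTH_STREAM])
    weights = np.asarray(cfg.n_protons_weights, dtype=float)
    weights = weights / weights.sum()
    molecules = []
    for i in range(cfg.n_molecules):
        n_groups = int(rng.integers(cfg.groups_range[0], cfg.groups_range[1] + 1))
        groups = []
        for _ in range(n_groups):
            shift = float(rng.uniform(*cfg.shift_range))
            n_protons = int(rng.choice(cfg.n_protons_choices, p=weights))
            couplings: tuple[tuple[float, int], ...] = ()
            if rng.random() < cfg.coupling_prob:
                j = float(rng.uniform(*cfg.j_range))
                n_partners = int(rng.integers(1, 4))
                couplings = ((j, n_partners),)
            groups.append(ProtonGroup(shift, n_protons, couplings))
        molecules.append(PredictionSet(f"syn{i + 1:04d}", tuple(groups)))
    return molecules


def perturb_predictions(
    truth: Sequence[PredictionSet], sigma_pred: float, seed: int
) -> list[PredictionSet]:
    """Add N(0, sigma_pred^2) noise to every shift; structure is preserved."""
    if sigma_pred < 0:
        raise ValueError("sigma_pred must be >= 0")
    rng = np.random.default_rng([seed, _PRED_STREAM])
    out = []
    for mol in truth:
        groups = tuple(
            ProtonGroup(
                g.shift + float(rng.normal(0.0, sigma_pred)) if sigma_pred > 0 else g.shift,
                g.n_protons,
                g.couplings,
            )
            for g in mol.groups
        )
        out.append(PredictionSet(mol.molecule_id, groups))
    return out


def make_experimental(
    truth: Sequence[PredictionSet],
    params: SimulationParams = SimulationParams(),
    noise: float = 0.01,
    seed: int = 0,
) -> list[Spectrum]:
    """Simulate each molecule and add uniform noise scaled to the peak height.

    Zero-mean uniform noise with peak-to-peak amplitude ``noise`` times the
    maximum intensity of the clean spectrum (the usual way a spectroscopist
    quotes baseline noise against the tallest peak); the result is clipped
    at zero and renormalised to unit total intensity.
    """
    rng = np.random.default_rng([seed, _NOISE_STREAM])
    spectra = []
    for mol in truth:
        s = simulate_spectrum(mol, params)
        if noise > 0:
            half = 0.5 * noise * float(s.intensities.max())
            y = s.intensities + rng.uniform(-half, half, s.n_points)
            s = normalize_total(s.with_intensities(np.clip(y, 0.0, None)))
        spectra.append(s)
    return spectra


def assignment_tables(
    truth: Sequence[PredictionSet], predicted: Sequence[PredictionSet]
) -> list[AssignmentTable]:
    """Pair truth and predicted shifts group-by-group into assignment tables.

    Valid because perturbation preserves group order; this mirrors the
    manual assignment step a traditional evaluation requires.
    """
    tables = []
    for t, p in zip(truth, predicted):
        if t.molecule_id != p.molecule_id or len(t.groups) != len(p.groups):
            raise ValueError(f"structure mismatch for '{t.molecule_id}'")
        pairs = tuple(
            (gt.shift, gp.shift) for gt, gp in zip(t.groups, p.groups)
        )
        tables.append(AssignmentTable(t.molecule_id, pairs))
    return tables
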