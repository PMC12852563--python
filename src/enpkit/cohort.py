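"""Seeded synthetic "experimental" cohort of ENP formulations.

Real formulation campaigns for exosome-mimetic nanoparticles concentrate in a
cholesterol-rich region of the five-lipid simplex (CHOL around 46%, PC 14–20%,
PE 12–16%). The generator draws compositions from a Dirichlet centered there
and labels them with a smooth ground-truth composition→CQA map whose sign
structure matches what is seen experimentally: PC fraction pushes size, PDI
and zeta potential all downward, PS dominates the (negative) surface charge,
and mild curvature/interaction terms make the map genuinely nonlinear.

The map is centered so the reference composition (46, 12, 18, 14, 10) yields
exactly size 120 nm, PDI 0.15, zeta −35 mV. Gaussian measurement noise
(sd 2 nm / 0.01 / 1 mV) is added when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import CQAS, LIPIDS, CQAVector, FormulationDataset, FormulationError, LipidComposition

#: reference composition at which the truth map hits (120 nm, 0.15, −35 mV)
REFERENCE_COMPOSITION = {"chol": 46.0, "sm": 12.0, "pc": 18.0, "pe": 14.0, "ps": 10.0}


class ConfigurationError(FormulationError):
    pass


@dataclass(frozen=True)
class TruthMapCoefficients:
    """Effect sizes of the ground-truth composition→CQA map.

    All PC coefficients are positive and enter with a minus sign, so the
    marginal effect of PC on every CQA is negative by construction.
    """

    size_pc: float = 1.2        # nm per mol% PC
    size_chol: float = 0.8      # nm per mol% CHOL
    size_pe_curv: float = 0.05  # nm per (mol% PE)^2, curvature term
    pdi_pc: float = 0.008       # PDI per mol% PC
    pdi_sm_curv: float = 0.0004  # PDI per (mol% SM)^2, convex term
    zeta_ps: float = 0.9        # mV per mol% PS
    zeta_pc: float = 0.55       # mV per mol% PC
    zeta_ps_pc: float = 0.03    # mV interaction, per (mol% PS)(mol% PC)
    pdi_floor: float = 0.01


@dataclass(frozen=True)
class CohortConfig:
    n_experimental: int = 225
    dirichlet_mean: tuple[float, ...] = (0.46, 0.12, 0.18, 0.14, 0.10)  # LIPIDS order
    dirichlet_concentration: float = 60.0
    noise_sd: tuple[float, float, float] = (2.0, 0.01, 1.0)  # size nm, pdi, zeta mV
    coefficients: TruthMapCoefficients = field(default_factory=TruthMapCoefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.dirichlet_mean, dtype=float)
        if mean.shape != (5,) or np.any(mean <= 0):
            raise ConfigurationError("dirichlet_mean needs five positive entries")
        if abs(mean.sum() - 1.0) > 1e-9:
            raise ConfigurationError("dirichlet_mean must sum to 1")
        if self.dirichlet_concentration <= 0:
            raise ConfigurationError("dirichlet_concentration must be positive")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ConfigurationError("all noise sds must be positive")
        if self.n_experimental < 10:
            raise ConfigurationError("n_experimental must be >= 10")


def sample_compositions(
    n: int, cfg: CohortConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` compositions (mol%, rows sum to 100) from the cohort Dirichlet."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    alpha = cfg.dirichlet_concentration * np.asarray(cfg.dirichlet_mean)
    fractions = rng.dirichlet(alpha, size=n)
    return fractions * 100.0


def ground_truth_cqa_array(
    compositions: np.ndarray,
    cfg: CohortConfig,
    with_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized truth map: (n, 5) compositions in mol% → (n, 3) CQA values."""
    c = cfg.coefficients
    comps = np.atleast_2d(np.asarray(compositions, dtype=float))
    chol, sm, pc, pe, ps = (comps[:, i] for i in range(5))
    d_chol = chol - REFERENCE_COMPOSITION["chol"]
    d_sm = sm - REFERENCE_COMPOSITION["sm"]
    d_pc = pc - REFERENCE_COMPOSITION["pc"]
    d_pe = pe - REFERENCE_COMPOSITION["pe"]
    d_ps = ps - REFERENCE_COMPOSITION["ps"]

    size = 120.0 - c.size_pc * d_pc + c.size_chol * d_chol + c.size_pe_curv * d_pe**2
    pdi = np.maximum(0.15 - c.pdi_pc * d_pc + c.pdi_sm_curv * d_sm**2, c.pdi_floor)
    zeta = -35.0 - c.zeta_ps * d_ps - c.zeta_pc * d_pc - c.zeta_ps_pc * d_ps * d_pc
    out = np.column_stack([size, pdi, zeta])

    if with_noise:
        rng = np.random.default_rng(cfg.seed) if rng is None else rng
        out = out + rng.normal(0.0, np.asarray(cfg.noise_sd), size=out.shape)
        out[:, 0] = np.maximum(out[:, 0], 1.0)
        out[:, 1] = np.maximum(out[:, 1], 0.0)
    return out


def ground_truth_cqa(
    composition: LipidComposition,
    cfg: CohortConfig,
    with_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> CQAVector:
    row = ground_truth_cqa_array(composition.as_array()[None, :], cfg, with_noise, rng)[0]
    return CQAVector(*row)


def make_experimental_set(cfg: CohortConfig | None = None) -> FormulationDataset:
    """Generate the default 225-record "experimental" cohort, seeded."""
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    comps = sample_compositions(cfg.n_experimental, cfg, rng)
    cqas = ground_truth_cqa_array(comps, cfg, with_noise=True, rng=rng)
    return FormulationDataset.from_arrays(comps, cqas, provenance="experimental")


def label_with_truth(
    compositions: np.ndarray,
    cfg: CohortConfig,
    with_noise: bool = True,
    seed: int | None = None,
    provenance: str = "gan_synthetic",
) -> FormulationDataset:
    """Attach truth-map CQA labels to externally generated compositions."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cqas = ground_truth_cqa_array(compositions, cfg, with_noise=with_noise, rng=rng)
    return FormulationDataset.from_arrays(compositions, cqas, provenance=provenance)
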