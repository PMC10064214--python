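"""Single-trait genetic architecture: QTL effects, TBV and phenotypes.

The trait is additive: the true breeding value of animal k is
``TBV_k = Σ_j β_j q_kj`` with q the allele-1 dosage (0/1/2) at QTL j.
Effect magnitudes are gamma-distributed with a small shape parameter
(many small, few large effects), signs are symmetric, and effects are
rescaled once so that the TBV variance in the base cohort of the selected
breeding step equals the target additive variance (h²·σ²_p).  Phenotypes
add a sex effect and a normal residual:
``y = μ + sex + TBV + ε``, ε ~ N(0, σ²_e).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap
from .presets import TraitConfig


@dataclass
class TraitArchitecture:
    """QTL positions (indices into the working genome) and additive effects."""

    qtl_idx: np.ndarray
    beta: np.ndarray
    h2: float
    var_p: float

    @property
    def var_a(self) -> float:
        return self.h2 * self.var_p

    @property
    def var_e(self) -> float:
        return self.var_p - self.var_a

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("QTL effects must be finite")
        if len(self.beta) != len(self.qtl_idx):
            raise ValueError("beta and qtl_idx length mismatch")


def sample_qtl_effects(n_qtl: int, shape: float, rng: np.random.Generator) -> np.ndarray:
    """Unscaled effects: Gamma(shape) magnitudes with random symmetric signs."""
    if n_qtl <= 0:
        raise ValueError("n_qtl must be positive")
    mag = rng.gamma(shape, 1.0, size=n_qtl)
    sign = rng.choice([-1.0, 1.0], size=n_qtl)
    return mag * sign


def calibrate_effects(beta_raw: np.ndarray, base_qtl_dosage: np.ndarray,
                      var_a: float) -> np.ndarray:
    """Rescale effects so the base cohort's TBV variance equals ``var_a``."""
    tbv = base_qtl_dosage @ beta_raw
    v = tbv.var()
    if v <= 0:
        raise ValueError("base cohort has zero TBV variance; cannot calibrate")
    return beta_raw * np.sqrt(var_a / v)


def make_architecture(gmap: GenomeMap, base_haplo: np.ndarray,
                      trait: TraitConfig, rng: np.random.Generator) -> TraitArchitecture:
    """Sample, symmetrise and calibrate QTL effects on the base cohort."""
    qtl = gmap.qtl_idx
    beta_raw = sample_qtl_effects(qtl.size, trait.gamma_shape, rng)
    dos = base_haplo[:, 0, :][:, qtl].astype(np.float64) + base_haplo[:, 1, :][:, qtl]
    beta = calibrate_effects(beta_raw, dos, trait.var_a)
    return TraitArchitecture(qtl_idx=qtl, beta=beta, h2=trait.h2, var_p=trait.var_p)


def true_breeding_values(haplo: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """TBV = QTL dosage · β for an (n, 2, L) haplotype block."""
    dos = haplo[:, 0, :][:, arch.qtl_idx].astype(np.float64) \
        + haplo[:, 1, :][:, arch.qtl_idx]
    return dos @ arch.beta


def simulate_phenotypes(tbv: np.ndarray, sex: np.ndarray, trait: TraitConfig,
                        rng: np.random.Generator) -> np.ndarray:
    """y = μ + sex effect (+ for males) + TBV + N(0, σ²_e)."""
    sex_eff = np.where(np.asarray(sex) == 0, trait.sex_effect, -trait.sex_effect)
    eps = rng.normal(0.0, np.sqrt(trait.var_e), size=len(tbv)) if trait.var_e > 0 \
        else np.zeros(len(tbv))
    return trait.mu + sex_eff + np.asarray(tbv) + eps
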