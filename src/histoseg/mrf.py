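"""MAP labelling of the feature image by a Markov random field.

The segmentation is the labelling ``omega`` maximizing the posterior
``P(omega | F) ∝ P(F | omega) P(omega)``: a per-site Gaussian likelihood of
the blue-channel feature given the class, times a Gibbs prior over pairwise
cliques that favours equal labels on neighbouring sites.  Minimizing the
corresponding energy

    U(omega) = sum_s [ log sigma_l + (f_s - mu_l)^2 / (2 sigma_l^2) ]
             + sum_{cliques {s,r}} V(omega_s, omega_r),

with the Potts potential ``V = -beta`` for equal labels and ``+beta``
otherwise, yields the MAP estimate.  ``beta`` weights the prior; 0.9 is the
working default.  Four relaxation schemes are provided — Metropolis
annealing (the default and empirically the best), modified Metropolis (MMD),
iterated conditional modes (ICM) and annealed Gibbs sampling — all starting
from the per-site maximum-likelihood labelling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .texture import ClassModel

#: Prior weight on the pairwise term; the working value for tissue cores.
DEFAULT_BETA = 0.9

HALF_LOG_2PI = 0.5 * math.log(2.0 * math.pi)

_OFFSETS_4 = np.array([(-1, 0), (1, 0), (0, -1), (0, 1)], dtype=np.int64)
_OFFSETS_8 = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
# Directed half of each neighbourhood: each unordered clique counted once.
_HALF_4 = np.array([(0, 1), (1, 0)], dtype=np.int64)
_HALF_8 = np.array([(0, 1), (1, 0), (1, 1), (1, -1)], dtype=np.int64)

#: Merged class order after collapsing the two non-tumour subtypes.
MERGED_CLASSES = ("tumour", "non_tumour", "background")


@dataclass(frozen=True)
class MRFConfig:
    """Relaxation configuration.

    ``t0``/``cooling``/``sweeps_per_temp`` define the geometric annealing
    schedule T <- cooling * T applied to the stochastic relaxers; ICM ignores
    it.  ``tol`` stops a run once the fraction of sites changed in a sweep
    drops below it.
    """

    beta: float = DEFAULT_BETA
    neighborhood: int = 8
    relaxer: str = "metropolis"
    t0: float = 4.0
    cooling: float = 0.98
    sweeps_per_temp: int = 1
    max_sweeps: int = 1000
    tol: float = 1e-4
    mmd_alpha: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.neighborhood not in (4, 8):
            raise ValueError("neighborhood must be 4 or 8")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.t0 <= 0:
            raise ValueError("initial temperature must be positive")
        if not 0 < self.mmd_alpha < 1:
            raise ValueError("mmd_alpha must lie in (0, 1)")
        if self.relaxer not in ("metropolis", "icm", "mmd", "gibbs"):
            raise ValueError(f"unknown relaxer {self.relaxer!r}")

    @property
    def offsets(self) -> np.ndarray:
        return _OFFSETS_8 if self.neighborhood == 8 else _OFFSETS_4

    @property
    def half_offsets(self) -> np.ndarray:
        return _HALF_8 if self.neighborhood == 8 else _HALF_4


@dataclass
class EnergyTrace:
    """Per-sweep bookkeeping of a relaxation run."""

    initial_energy: float
    energy: list[float] = field(default_factory=list)
    change_fraction: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_sweeps(self) -> int:
        return len(self.energy)


def singleton_energy(
    f: np.ndarray | float, class_index: int, model: ClassModel
) -> np.ndarray | float:
    """Negative log Gaussian density of feature f under the class model.

    ``log sigma + (f - mu)^2 / (2 sigma^2) + log(2 pi)/2`` — the constant is
    retained so the energy is the exact negative log density (it cancels in
    label comparisons).
    """
    mu = model.means[class_index]
    var = model.variances[class_index]
    return 0.5 * np.log(var) + (np.asarray(f, dtype=float) - mu) ** 2 / (2.0 * var) + HALF_LOG_2PI


def clique_potential(label_s, label_r, beta: float):
    """Potts pairwise potential: -beta for equal labels, +beta otherwise."""
    return np.where(np.equal(label_s, label_r), -beta, beta)


def singleton_energy_field(features: np.ndarray, model: ClassModel) -> np.ndarray:
    """H x W x k array of singleton energies for every site and class."""
    f = np.asarray(features, dtype=float)[..., None]
    mu = model.means[None, None, :]
    var = model.variances[None, None, :]
    return 0.5 * np.log(var) + (f - mu) ** 2 / (2.0 * var) + HALF_LOG_2PI


def local_energy(
    site: tuple[int, int],
    class_index: int,
    labels: np.ndarray,
    features: np.ndarray,
    model: ClassModel,
    config: MRFConfig,
) -> float:
    """Singleton energy at a site plus Potts terms to all its neighbours."""
    i, j = site
    h, w = labels.shape
    e = float(singleton_energy(features[i, j], class_index, model))
    for di, dj in config.offsets:
        ni, nj = i + di, j + dj
        if 0 <= ni < h and 0 <= nj < w:
            e += float(clique_potential(class_index, labels[ni, nj], config.beta))
    return e


def total_energy(
    labels: np.ndarray,
    features: np.ndarray,
    model: ClassModel,
    config: MRFConfig,
) -> float:
    """Global energy: all singletons plus each unordered clique once."""
    labels = np.asarray(labels)
    energies = singleton_energy_field(features, model)
    idx = np.indices(labels.shape)
    u = float(energies[idx[0], idx[1], labels].sum())
    h, w = labels.shape
    for di, dj in config.half_offsets:
        a = labels[max(0, -di) : h - max(0, di), max(0, -dj) : w - max(0, dj)]
        b = labels[max(0, di) : h - max(0, -di), max(0, dj) : w - max(0, -dj)]
        if a.size:
            u += float(clique_potential(a, b, config.beta).sum())
    return u


def gibbs_conditional(
    site: tuple[int, int],
    labels: np.ndarray,
    features: np.ndarray,
    model: ClassModel,
    config: MRFConfig,
    temperature: float,
) -> np.ndarray:
    """Local conditional label distribution exp(-U_local/T), normalized."""
    local = np.array(
        [
            local_energy(site, lam, labels, features, model, config)
            for lam in range(model.n_classes)
        ]
    )
    p = np.exp(-(local - local.min()) / temperature)
    return p / p.sum()


def ml_labelling(features: np.ndarray, model: ClassModel) -> np.ndarray:
    """Per-site maximum-likelihood labelling (singleton argmin; ties -> smallest)."""
    return np.argmin(singleton_energy_field(features, model), axis=2).astype(np.int64)


def _relax(features: np.ndarray, model: ClassModel, config: MRFConfig):
    features = np.asarray(features, dtype=float)
    energies = np.ascontiguousarray(singleton_energy_field(features, model))
    labels = np.ascontiguousarray(ml_labelling(features, model))
    h, w = labels.shape
    n = h * w
    k = model.n_classes
    offsets = np.ascontiguousarray(config.offsets)
    rng = np.random.default_rng(config.seed)
    current = total_energy(labels, features, model, config)
    trace = EnergyTrace(initial_energy=current)
    best_energy = current
    best_labels = labels.copy()
    stochastic = config.relaxer != "icm"
    log_alpha = math.log(config.mmd_alpha)

    for sweep in range(config.max_sweeps):
        temperature = config.t0 * config.cooling ** (sweep // config.sweeps_per_temp)
        if config.relaxer == "icm":
            delta, changed = _kernels.icm_sweep(labels, energies, config.beta, offsets)
        else:
            order = rng.permutation(n)
            if config.relaxer == "metropolis":
                proposals = rng.integers(0, k - 1, size=n)
                uniforms = rng.random(n)
                delta, changed = _kernels.metropolis_sweep(
                    labels, energies, config.beta, temperature, offsets,
                    order, proposals, uniforms,
                )
            elif config.relaxer == "mmd":
                proposals = rng.integers(0, k - 1, size=n)
                delta, changed = _kernels.mmd_sweep(
                    labels, energies, config.beta, temperature, offsets,
                    order, proposals, log_alpha,
                )
            else:  # gibbs
                uniforms = rng.random(n)
                delta, changed = _kernels.gibbs_sweep(
                    labels, energies, config.beta, temperature, offsets,
                    order, uniforms,
                )
        current += delta
        trace.energy.append(current)
        trace.change_fraction.append(changed / n)
        trace.temperature.append(temperature if stochastic else 0.0)
        if current < best_energy:
            best_energy = current
            best_labels = labels.copy()
        if changed / n < config.tol:
            trace.converged = True
            break
    if not trace.converged:
        warnings.warn(
            f"{config.relaxer} did not converge in {config.max_sweeps} sweeps; "
            "returning best labelling found",
            stacklevel=3,
        )
    return (best_labels if stochastic else labels), trace


def relax_metropolis(features, model, config: MRFConfig | None = None):
    """Simulated annealing with Metropolis acceptance (the default relaxer)."""
    config = replace(config or MRFConfig(), relaxer="metropolis")
    return _relax(features, model, config)


def relax_icm(features, model, config: MRFConfig | None = None):
    """Iterated conditional modes: deterministic greedy coordinate descent."""
    config = replace(config or MRFConfig(), relaxer="icm")
    return _relax(features, model, config)


def relax_mmd(features, model, config: MRFConfig | None = None):
    """Modified Metropolis with a fixed acceptance threshold alpha."""
    config = replace(config or MRFConfig(), relaxer="mmd")
    return _relax(features, model, config)


def relax_gibbs(features, model, config: MRFConfig | None = None):
    """Annealed Gibbs sampling from the local conditionals."""
    config = replace(config or MRFConfig(), relaxer="gibbs")
    return _relax(features, model, config)


def relax(features, model, config: MRFConfig):
    """Dispatch to the relaxer named in the configuration."""
    return _relax(features, model, config)


def merge_non_tumour(labels: np.ndarray) -> np.ndarray:
    """Collapse stroma and lymphoid/necrosis into one non-tumour class.

    Input labels follow the four-class order (tumour=0, stroma=1,
    lymphoid/necrosis=2, background=3); output follows
    :data:`MERGED_CLASSES` (tumour=0, non_tumour=1, background=2).
    """
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=0) > 3:
        bad = sorted(set(np.unique(labels)) - {0, 1, 2, 3})
        raise ValueError(f"unknown labels in four-class labelling: {bad}")
    mapping = np.array([0, 1, 1, 2], dtype=labels.dtype)
    return mapping[labels]
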