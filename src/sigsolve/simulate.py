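"""Multinomial simulation of mutation catalogs from signature mixtures.

Each sample's mutations are drawn from a single multinomial whose channel
probabilities are the exposure-weighted mixture of the panel's signature
rows — SNVs generated by the operative mutational processes, with success
probabilities proportional to each process's emission. Presets mirror three
cohort structures used throughout the package's simulation studies over six
signatures: one dominant process (scenario A), two dominant processes
(scenario B), and all processes contributing equally (scenario C), at 15/25/50
samples and 500–35,000 mutations per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .catalog import CountMatrix
from .fitting import ExposureMatrix
from .panel import SignaturePanel
from .synthetic_panels import SIX_SIGNATURE_NAMES

__all__ = [
    "SimulationSpec",
    "simulate_catalog",
    "scenario_preset",
    "dirichlet_fractions",
    "SCENARIO_FRACTIONS",
    "MUTATION_GRID",
]

_WEIGHT_TOL = 1e-9

#: Default per-sample mutation burdens used in the simulation grids.
MUTATION_GRID = (500, 1000, 2500, 5000, 20000, 35000)

#: Cohort exposure fractions per scenario, over the six preset signatures.
SCENARIO_FRACTIONS = {
    "A": (0.75, 0.05, 0.05, 0.05, 0.05, 0.05),
    "B": (0.375, 0.375, 0.0625, 0.0625, 0.0625, 0.0625),
    "C": (1 / 6,) * 6,
}


@dataclass
class SimulationSpec:
    """Everything needed to draw one synthetic cohort.

    ``exposure_fractions`` is either one weight vector over the panel's
    signatures (cohort-level, shared by all samples) or an
    ``n_samples × n_signatures`` array of per-sample weights; each weight
    vector sums to one.
    """

    panel: SignaturePanel
    exposure_fractions: np.ndarray = field(repr=False)
    n_samples: int = 25
    n_mutations: int = 5000
    seed: int = 0
    per_signature_draws: bool = False

    def __post_init__(self) -> None:
        w = np.atleast_2d(np.asarray(self.exposure_fractions, dtype=float))
        if w.shape[1] != self.panel.n_signatures:
            raise ValueError(
                f"{w.shape[1]} weights for {self.panel.n_signatures} signatures"
            )
        if w.shape[0] not in (1, self.n_samples):
            raise ValueError("weights must be cohort-level or one row per sample")
        if np.any(w < 0):
            raise ValueError("negative exposure fraction")
        sums = w.sum(axis=1)
        if np.any(sums == 0):
            raise ValueError("zero total exposure weight")
        if np.any(np.abs(sums - 1.0) > _WEIGHT_TOL):
            raise ValueError(f"exposure fractions must sum to 1 within {_WEIGHT_TOL}")
        self.exposure_fractions = w / sums[:, None]
        if self.n_samples < 1 or self.n_mutations < 1:
            raise ValueError("n_samples and n_mutations must be >= 1")

    @property
    def sample_weights(self) -> np.ndarray:
        """(n_samples, n_signatures) weights, broadcasting the cohort vector."""
        w = self.exposure_fractions
        return np.broadcast_to(w, (self.n_samples, w.shape[1])).copy() if w.shape[0] == 1 else w


def simulate_catalog(spec: SimulationSpec) -> tuple[CountMatrix, ExposureMatrix]:
    """Draw a synthetic catalog and return it with its ground-truth exposures.

    Per sample, the channel distribution is ``weightsᵀ · panel.probs`` and
    the counts are one multinomial draw of size ``n_mutations`` (with
    ``per_signature_draws`` set, one multinomial per signature instead —
    identical in distribution, but integer per-signature truths). The
    returned exposures are the expected per-signature attributions,
    ``fraction × n_mutations`` (or the realised integers in per-signature
    mode). Reproducible from ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    W = spec.sample_weights
    H = spec.panel.probs
    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    counts = np.zeros((spec.n_samples, H.shape[1]), dtype=np.int64)
    truth = W * spec.n_mutations

    if spec.per_signature_draws:
        truth = np.zeros_like(W)
        for i in range(spec.n_samples):
            n_per_sig = rng.multinomial(spec.n_mutations, W[i])
            truth[i] = n_per_sig
            for k, n in enumerate(n_per_sig):
                if n:
                    counts[i] += rng.multinomial(n, H[k])
    else:
        for i in range(spec.n_samples):
            counts[i] = rng.multinomial(spec.n_mutations, W[i] @ H)

    A = CountMatrix(samples, spec.panel.catalog, counts)
    W_true = ExposureMatrix(samples, list(spec.panel.names), truth.astype(float))
    return A, W_true


def dirichlet_fractions(
    fractions, n_samples: int, concentration: float, seed
) -> np.ndarray:
    """Per-sample exposure fractions jittered around a cohort mean.

    Rows are drawn from Dirichlet(concentration × fractions): the cohort
    mean stays at ``fractions`` while individual samples vary, emulating
    inter-patient heterogeneity of process activity. Larger ``concentration``
    means tighter cohorts (at 50, fractions vary by roughly ±30% relative).
    """
    fractions = np.asarray(fractions, dtype=float)
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    return rng.dirichlet(concentration * fractions, size=n_samples)


def scenario_preset(
    name: str,
    n_samples: int = 25,
    n_mutations: int = 5000,
    seed: int = 0,
    *,
    panel: SignaturePanel,
    heterogeneity: float | None = None,
) -> SimulationSpec:
    """Simulation spec for scenario A, B or C over the six preset signatures.

    ``panel`` must contain the six signatures named in
    :data:`~sigsolve.synthetic_panels.SIX_SIGNATURE_NAMES`; the spec is built
    over exactly those six, with the scenario's dominance structure
    (:data:`SCENARIO_FRACTIONS`). By default every sample shares the
    scenario's cohort fractions exactly; with ``heterogeneity`` set, each
    sample's fractions are a Dirichlet draw centred on them
    (:func:`dirichlet_fractions`), which is what makes multi-signature
    de novo recovery identifiable.
    """
    name = name.upper()
    if name not in SCENARIO_FRACTIONS:
        raise ValueError(f"unknown scenario {name!r}; expected A, B or C")
    missing = [s for s in SIX_SIGNATURE_NAMES if s not in panel.names]
    if missing:
        raise ValueError(f"panel lacks required signature(s): {missing}")
    sub = panel.subset(list(SIX_SIGNATURE_NAMES))
    fractions = np.array(SCENARIO_FRACTIONS[name])
    if heterogeneity is not None:
        fractions = dirichlet_fractions(fractions, n_samples, heterogeneity, seed)
    return SimulationSpec(
        panel=sub,
        exposure_fractions=fractions,
        n_samples=n_samples,
        n_mutations=n_mutations,
        seed=seed,
    )
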