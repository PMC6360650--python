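"""Synthetic nanopore signal data with known modified positions.

Generates paired read groups over a random reference: every position's
signals are drawn from the normal distribution of the 5-mer centered on
it (mean ``E_k``, standard deviation ``D_k`` from a pore model), with a
per-read, per-position measurement count drawn uniformly from 5..15 plus
a small additive Gaussian noise.  In the modified group, ``h`` randomly
chosen positions carry modifications that inflate the mean by a factor
``(1 + w_a)`` and the standard deviation by ``(1 + w_b)``; under the
neighborhood-effect scenario the perturbation leaks into positions within
two bases, decaying as ``w_a = alpha / 2**d`` and ``w_b = beta / (d+1)``
with distance ``d``, and adds up when two modifications are near.

Four scenarios gate which perturbations are active:

========================  =====================  ==================
scenario                  modified position      neighbors (d<=2)
========================  =====================  ==================
``MeanDif``               mean only              none
``STDDif``                sd only                none
``Mean_STDDif``           mean and sd            none
``Mean_STDDif_NE``        mean and sd            mean and sd, decayed
========================  =====================  ==================

The generator also serves as the package's test-fixture factory; an
option injects synthetic basecalling indels so the event corrector can be
exercised on reads whose true alignment is known.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .event_correction import AlignmentOp
from .signal_model import EventSequence, PoreModel

__all__ = [
    "SCENARIOS",
    "ScenarioConfig",
    "PerturbationWeights",
    "make_pore_model",
    "random_reference",
    "perturbation_weights",
    "perturbation_arrays",
    "simulate_read",
    "simulate_dataset",
    "inject_indels",
]

SCENARIOS = ("MeanDif", "STDDif", "Mean_STDDif", "Mean_STDDif_NE")

#: Synthetic pore-model ranges (picoamperes), chosen to resemble the
#: level span and spread of published 5-mer models.
_MODEL_MEAN_RANGE = (70.0, 130.0)
_MODEL_SD_RANGE = (1.0, 3.0)

#: Distance beyond which a modification no longer perturbs a position.
NEIGHBOR_RADIUS = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulation scenario.

    ``alpha`` scales the relative mean shift, ``beta`` the relative
    standard-deviation inflation at a modified position.
    ``signals_per_position`` gives the inclusive bounds of the uniform
    per-read, per-position measurement count.  ``noise_sd_frac`` sets the
    additive Gaussian noise to this fraction of the 5-mer standard
    deviation (0 disables it).
    """

    scenario: str = "Mean_STDDif_NE"
    alpha: float = 0.2
    beta: float = 1.0
    n_modifications: int = 60
    reads_per_group: int = 100
    signals_per_position: tuple[int, int] = (5, 15)
    reference_length: int = 6184
    n_datasets: int = 1
    seed: int | None = None
    noise_sd_frac: float = 0.05
    k: int = 5

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}"
            )
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        lo, hi = self.signals_per_position
        if lo < 1 or hi < lo:
            raise ValueError("signals_per_position bounds must satisfy 1 <= lo <= hi")
        if self.n_modifications > self.reference_length - (self.k - 1):
            raise ValueError("more modifications than eligible reference positions")

    @property
    def neighborhood_effect(self) -> bool:
        return self.scenario == "Mean_STDDif_NE"

    @property
    def effective_alpha(self) -> float:
        """alpha after scenario gating (STDDif switches the mean shift off)."""
        return 0.0 if self.scenario == "STDDif" else self.alpha

    @property
    def effective_beta(self) -> float:
        """beta after scenario gating (MeanDif switches the sd inflation off)."""
        return 0.0 if self.scenario == "MeanDif" else self.beta


@dataclass(frozen=True)
class PerturbationWeights:
    """Relative mean shift and sd inflation at one position."""

    w_a: float
    w_b: float


def make_pore_model(k: int = 5, seed: int | None = None) -> PoreModel:
    """A synthetic pore model covering all ``4**k`` k-mers.

    Means are drawn uniformly from a picoampere-like level range and
    standard deviations from a strictly positive spread range; the table
    is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    means = rng.uniform(*_MODEL_MEAN_RANGE, size=len(kmers))
    sds = rng.uniform(*_MODEL_SD_RANGE, size=len(kmers))
    return PoreModel(k, {km: (float(m), float(s)) for km, m, s in zip(kmers, means, sds)})


def random_reference(length: int, rng: np.random.Generator) -> str:
    """A uniform random nucleotide sequence."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def perturbation_weights(
    mod_positions: set[int] | frozenset[int],
    query: int,
    alpha: float,
    beta: float,
) -> PerturbationWeights:
    """Summed perturbation at ``query`` from all modifications within 2 bases.

    Each modification at distance ``d <= 2`` contributes
    ``alpha / 2**d`` to the mean weight and ``beta / (d + 1)`` to the sd
    weight; contributions from multiple nearby modifications add.
    """
    w_a = w_b = 0.0
    for d in range(NEIGHBOR_RADIUS + 1):
        for pos in ({query} if d == 0 else {query - d, query + d}):
            if pos in mod_positions:
                w_a += alpha / 2**d
                w_b += beta / (d + 1)
    return PerturbationWeights(w_a, w_b)


def perturbation_arrays(
    mod_positions: np.ndarray, length: int, config: ScenarioConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position (w_a, w_b) arrays under the scenario's gating."""
    w_a = np.zeros(length)
    w_b = np.zeros(length)
    alpha = config.effective_alpha
    beta = config.effective_beta
    radius = NEIGHBOR_RADIUS if config.neighborhood_effect else 0
    for pos in np.asarray(mod_positions, dtype=np.int64):
        for d in range(radius + 1):
            for q in ({pos} if d == 0 else {pos - d, pos + d}):
                if 0 <= q < length:
                    w_a[q] += alpha / 2**d
                    w_b[q] += beta / (d + 1)
    return w_a, w_b


def _model_arrays(reference: str, pore_model: PoreModel) -> tuple[np.ndarray, np.ndarray]:
    means = pore_model.means_for(reference)
    sds = pore_model.sds_for(reference)
    return means, sds


def _simulate_read_fast(
    read_id: str,
    start: int,
    means: np.ndarray,
    sds: np.ndarray,
    noise_sds: np.ndarray,
    count_bounds: tuple[int, int],
    bases: str,
    rng: np.random.Generator,
) -> EventSequence:
    """Draw one read given precomputed per-position mean/sd arrays."""
    lo, hi = count_bounds
    counts = rng.integers(lo, hi + 1, size=means.size)
    # additive independent Gaussian noise folded into the draw's scale
    sd_eff = np.sqrt(np.repeat(sds, counts) ** 2 + np.repeat(noise_sds, counts) ** 2)
    signals = rng.normal(np.repeat(means, counts), sd_eff)
    return EventSequence(
        read_id, "+", start, bases, signals, counts, position_map=None, normalized=False
    )


def simulate_read(
    reference: str,
    pore_model: PoreModel,
    mod_positions: set[int] | np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
    modified: bool = True,
    read_id: str = "read",
) -> EventSequence:
    """Simulate one read spanning every position with full k-mer context.

    Unmodified reads use ``w_a = w_b = 0`` everywhere; modified reads
    apply the scenario-gated perturbations at (and, with neighborhood
    effect, around) the modified positions.
    """
    half = pore_model.k // 2
    start, end = half, len(reference) - (pore_model.k - half) + 1
    means, sds = _model_arrays(reference, pore_model)
    means, sds = means[start:end], sds[start:end]
    if modified:
        w_a, w_b = perturbation_arrays(
            np.asarray(sorted(mod_positions), dtype=np.int64), len(reference), config
        )
        means = means * (1.0 + w_a[start:end])
        sds = sds * (1.0 + w_b[start:end])
    noise = config.noise_sd_frac * _model_arrays(reference, pore_model)[1][start:end]
    return _simulate_read_fast(
        read_id,
        start,
        means,
        sds,
        noise,
        config.signals_per_position,
        reference[start:end],
        rng,
    )


def simulate_dataset(
    config: ScenarioConfig,
    reference: str | None = None,
    pore_model: PoreModel | None = None,
) -> tuple[list[EventSequence], list[EventSequence], set[int], str, PoreModel]:
    """Generate one paired dataset.

    Returns ``(modified_reads, control_reads, truth, reference,
    pore_model)`` where ``truth`` is the set of modified positions.
    Fully reproducible from ``config.seed``; a reference and/or pore
    model may be supplied to share them across replicate datasets.
    """
    rng = np.random.default_rng(config.seed)
    if pore_model is None:
        pore_model = make_pore_model(config.k, seed=rng.integers(2**31))
    if reference is None:
        reference = random_reference(config.reference_length, rng)
    half = pore_model.k // 2
    start, end = half, len(reference) - (pore_model.k - half) + 1

    eligible = np.arange(start, end)
    truth = rng.choice(eligible, size=config.n_modifications, replace=False)
    truth_set = {int(p) for p in truth}

    means, sds = _model_arrays(reference, pore_model)
    means, sds = means[start:end], sds[start:end]
    noise = config.noise_sd_frac * sds
    w_a, w_b = perturbation_arrays(truth, len(reference), config)
    mod_means = means * (1.0 + w_a[start:end])
    mod_sds = sds * (1.0 + w_b[start:end])

    bases = reference[start:end]
    bounds = config.signals_per_position
    control = [
        _simulate_read_fast(
            f"ctrl_{i:04d}", start, means, sds, noise, bounds, bases, rng
        )
        for i in range(config.reads_per_group)
    ]
    modified = [
        _simulate_read_fast(
            f"mod_{i:04d}", start, mod_means, mod_sds, noise, bounds, bases, rng
        )
        for i in range(config.reads_per_group)
    ]
    return modified, control, truth_set, reference, pore_model


def inject_indels(
    read: EventSequence,
    rng: np.random.Generator,
    insertion_rate: float = 0.02,
    deletion_rate: float = 0.02,
) -> tuple[EventSequence, list[AlignmentOp]]:
    """Corrupt a clean read with synthetic basecalling indels.

    A deletion merges an event's signals into its predecessor (the base
    disappears from the called sequence); an insertion splits an event in
    two, the spurious half receiving a random base.  Total signal count
    is conserved, so the true alignment — returned alongside the read —
    lets the corrector restore one event per reference position.
    """
    if read.position_map is not None:
        raise ValueError("indel injection expects an uncorrected, unshared read")
    off = read.offsets
    new_signals: list[np.ndarray] = []
    new_bases: list[str] = []
    cigar: list[str] = []  # one symbol per output event / deleted position
    for t in range(read.n_events):
        sig = read.signals[off[t] : off[t] + read.lengths[t]]
        r = rng.random()
        if r < deletion_rate and new_signals and cigar[-1] != "D":
            new_signals[-1] = np.concatenate([new_signals[-1], sig])
            cigar.append("D")
        elif r < deletion_rate + insertion_rate and sig.size >= 2:
            cut = int(rng.integers(1, sig.size))
            new_signals.append(sig[:cut])
            new_bases.append("ACGT"[rng.integers(0, 4)])
            cigar.append("I")
            new_signals.append(sig[cut:])
            new_bases.append(read.bases[t])
            cigar.append("M")
        else:
            new_signals.append(sig)
            new_bases.append(read.bases[t])
            cigar.append("M")

    ops: list[AlignmentOp] = []
    read_i = 0
    ref_i = read.aligned_ref_start
    for sym, group in itertools.groupby(cigar):
        length = len(list(group))
        if sym == "M":
            ops.append(AlignmentOp("match", length, read_i, ref_i))
            read_i += length
            ref_i += length
        elif sym == "I":
            ops.append(AlignmentOp("insertion", length, read_i, ref_i))
            read_i += length
        else:
            ops.append(AlignmentOp("deletion", length, read_i, ref_i))
            ref_i += length

    corrupted = EventSequence(
        read.read_id,
        read.strand,
        read.aligned_ref_start,
        "".join(new_bases),
        np.concatenate(new_signals),
        np.array([s.size for s in new_signals], dtype=np.int64),
        position_map=None,
        normalized=read.normalized,
    )
    return corrupted, ops
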