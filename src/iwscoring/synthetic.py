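"""Synthetic score matrices, labels, positions and reference pools.

The generator emulates the statistical skeleton the weighting scheme assumes:
a latent functional state per variant (Bernoulli prevalence), a latent
continuous signal shifted in the functional class, per-system emissions
``a_i * signal + noise`` whose loadings a_i play the role of system
informativeness, residual noise with a block-correlation structure (one tight
five-system block and one moderate three-system block, mirroring the observed
grouping of the real panels), and per-system MCAR missingness. Nothing about
the real systems' marginal score distributions is emulated.

All randomness flows through NumPy's PCG64 generator seeded from the config,
so every output is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_SYSTEM_SPECS, ScoreMatrix, SystemSpec, ValidationError, VariantKey

_SYSTEMS = tuple(s.id for s in DEFAULT_SYSTEM_SPECS)


def identity_system_specs(systems) -> dict[str, SystemSpec]:
    """Identity-transform specs for generated matrices.

    Generated scores live directly on the integration scale (there is no
    p-value-scaled column to -log2-transform), so models trained on them
    should bypass the canonical per-system transforms. The canonical
    known-variants-only flags are preserved.
    """
    known = {sp.id: sp.known_only for sp in DEFAULT_SYSTEM_SPECS}
    return {s: SystemSpec(s, known_only=known.get(s, False)) for s in systems}

#: Signal loadings: the tightly correlated block (eigen, deepsea, fathmm_mkl,
#: remm, cadd) carries the strongest signal, the purely evolutionary system
#: the weakest, echoing the qualitative ordering seen on real panels.
DEFAULT_LOADINGS: dict[str, float] = {
    "eigen": 1.0,
    "deepsea": 0.95,
    "fathmm_mkl": 0.9,
    "remm": 0.85,
    "cadd": 0.8,
    "funseq2": 0.6,
    "gwava_region": 0.55,
    "gwava_unmatched": 0.5,
    "eigen_pc": 0.45,
    "gwava_tss": 0.4,
    "fitcons": 0.35,
}

#: Residual-correlation blocks: (member systems, within-block correlation).
DEFAULT_BLOCKS: tuple[tuple[tuple[str, ...], float], ...] = (
    (("eigen", "deepsea", "fathmm_mkl", "remm", "cadd"), 0.6),
    (("gwava_region", "gwava_tss", "gwava_unmatched"), 0.3),
)

#: MCAR missingness per system: most systems cover ~95% of variants, the
#: annotation-hungry ones less, down to slightly over half for the worst.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "cadd": 0.05,
    "deepsea": 0.05,
    "eigen": 0.09,
    "eigen_pc": 0.13,
    "fitcons": 0.05,
    "funseq2": 0.45,
    "fathmm_mkl": 0.05,
    "gwava_region": 0.11,
    "gwava_tss": 0.11,
    "gwava_unmatched": 0.11,
    "remm": 0.05,
}


@dataclass
class SimulationConfig:
    """Parameters of the two-class latent-signal generative model."""

    n_variants: int = 10_000
    systems: tuple[str, ...] = _SYSTEMS
    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    blocks: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_BLOCKS
    missing_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    prevalence: float = 0.1
    class_shift: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValidationError("prevalence must lie in (0, 1)")
        for s in self.systems:
            rate = self.missing_rates.get(s, 0.0)
            if not (0 <= rate < 1):
                raise ValidationError(f"missing rate for {s!r} must lie in [0, 1)")
            if s not in self.loadings:
                raise ValidationError(f"no loading given for system {s!r}")

    def residual_correlation(self) -> np.ndarray:
        """Residual noise correlation implied by the block structure."""
        k = len(self.systems)
        R = np.eye(k)
        index = {s: i for i, s in enumerate(self.systems)}
        for members, r in self.blocks:
            idx = [index[m] for m in members if m in index]
            for a in idx:
                for b in idx:
                    if a != b:
                        R[a, b] = r
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValidationError("block correlation structure is not positive definite")
        return R

    def loading_vector(self) -> np.ndarray:
        return np.array([self.loadings[s] for s in self.systems], dtype=float)


def _keys(n: int, chrom: str = "chr1", start: int = 1) -> list[VariantKey]:
    return [VariantKey(chrom, start + i, "A", "T") for i in range(n)]


def generate_two_class_scores(config: SimulationConfig
                              ) -> tuple[ScoreMatrix, np.ndarray, np.ndarray]:
    """Draw a score matrix with labels and the latent signal.

    Returns ``(matrix, labels, signal)``: labels are 0/1, the signal is
    N(class_shift * label, 1), and system i emits
    ``loadings[i] * signal + block-correlated unit-variance noise`` with MCAR
    masking at the per-system rates.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    a = config.loading_vector()
    R = config.residual_correlation()
    L = np.linalg.cholesky(R)

    labels = (rng.random(n) < config.prevalence).astype(int)
    signal = config.class_shift * labels + rng.standard_normal(n)
    noise = rng.standard_normal((n, len(config.systems))) @ L.T
    values = signal[:, None] * a[None, :] + noise

    for j, s in enumerate(config.systems):
        rate = config.missing_rates.get(s, 0.0)
        if rate > 0:
            values[rng.random(n) < rate, j] = np.nan

    matrix = ScoreMatrix(_keys(n), list(config.systems), values)
    return matrix, labels, signal


def generate_reference_pool(config: SimulationConfig, n: int) -> ScoreMatrix:
    """A complete-case draw of ``n`` rows from the same generative model."""
    if n < 1:
        raise ValidationError("pool size must be >= 1")
    cfg = SimulationConfig(
        n_variants=n, systems=config.systems, loadings=dict(config.loadings),
        blocks=config.blocks, missing_rates={s: 0.0 for s in config.systems},
        prevalence=config.prevalence, class_shift=config.class_shift,
        seed=config.seed,
    )
    matrix, _, _ = generate_two_class_scores(cfg)
    return matrix


def generate_positions(n: int, n_clusters: int, cluster_width: int,
                       chrom_length: int, seed: int = 0, cluster_size: int = 3,
                       guard_gap: int = 10_000) -> tuple[np.ndarray, list[np.ndarray]]:
    """Positions with planted clusters among sparse background positions.

    ``n_clusters`` groups of ``cluster_size`` positions are planted with
    intra-cluster gaps below ``guard_gap``; background positions and cluster
    flanks are kept at least ``guard_gap`` apart, so cluster detection at the
    same gap threshold recovers exactly the planted groups. Returns the
    sorted position vector and the list of planted member-position arrays.
    """
    if cluster_width >= chrom_length:
        raise ValidationError("cluster_width must be smaller than chrom_length")
    if n < n_clusters * cluster_size:
        raise ValidationError("n is too small for the requested clusters")
    if n_clusters and cluster_width < cluster_size - 1:
        raise ValidationError("cluster_width too narrow for cluster_size distinct positions")
    rng = np.random.default_rng(seed)

    n_background = n - n_clusters * cluster_size
    unit_lengths = [cluster_width] * n_clusters + [1] * n_background
    n_units = len(unit_lengths)
    required = sum(unit_lengths) + (n_units + 1) * guard_gap
    if required > chrom_length:
        raise ValidationError(
            f"cannot pack {n_units} separated units into chrom_length={chrom_length} "
            f"(need >= {required})"
        )

    # shuffle unit order, then distribute the spare length over the gaps
    order = rng.permutation(n_units)
    spare = chrom_length - required
    cuts = np.sort(rng.integers(0, spare + 1, size=n_units))
    extra = np.diff(np.concatenate([[0], cuts, [spare]]))
    gaps = guard_gap + extra

    positions: list[int] = []
    truth: list[np.ndarray] = []
    cursor = 0
    for u, gap in zip(order, gaps[:-1]):
        cursor += int(gap)
        if u < n_clusters:  # a cluster unit
            offsets = np.sort(rng.choice(cluster_width + 1, size=cluster_size, replace=False))
            members = cursor + offsets
            if np.diff(members).max(initial=0) >= guard_gap:
                # resample densely: space members evenly inside the width
                members = cursor + np.linspace(0, cluster_width, cluster_size).astype(int)
            positions.extend(int(p) for p in members)
            truth.append(np.asarray(sorted(int(p) for p in members)))
            cursor += cluster_width
        else:
            positions.append(cursor)
            cursor += 1

    pos = np.sort(np.asarray(positions, dtype=int)) + 1  # 1-based
    truth = [t + 1 for t in truth]
    if pos.min() < 1 or pos.max() > chrom_length:
        raise ValidationError("internal packing error: positions escaped the chromosome")
    return pos, sorted(truth, key=lambda t: int(t[0]))
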