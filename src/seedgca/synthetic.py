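"""Synthetic resting-state cohorts with planted directed coupling.

The generator produces desk-scale data with the statistical structure
the analysis pipeline assumes: a small set of regional signals following
a stationary lag-1 vector autoregression (VAR(1)) with Gaussian
innovations, embedded as spatial blocks in a 4-D phantom volume together
with independent white-matter / CSF nuisance signals, linear scanner
drift, a motion-correlated component, per-volume rigid-body motion
traces, and a subject table whose avoidance score is linearly tied to
each subject's realized coupling strength.

Two groups ("SAD" patients and "HC" controls) differ by an additive
delta on selected coupling entries; each subject's couplings are further
jittered around the group mean so that between-subject correlations with
clinical scores are well defined.  All randomness flows from a single
master seed through ``numpy.random.SeedSequence`` spawning, so an
identical seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .group_stats import SubjectRecord
from .preprocess import MotionTrace

__all__ = [
    "NetworkSpec",
    "ScoreModel",
    "CohortConfig",
    "SubjectData",
    "Cohort",
    "simulate_coupled_var",
    "build_phantom",
    "simulate_motion_trace",
    "synthesize_cohort",
    "default_network",
    "default_cohort_config",
]

#: Samples discarded before recording a VAR realization.
BURN_IN = 200

Block = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass
class NetworkSpec:
    """A stationary lag-1 linear network of regional signals.

    ``coupling[i, j]`` is the weight of node i's past on node j's present;
    the diagonal must be zero (self terms live in ``self_coefficients``).
    The full lag-1 transition matrix is ``diag(self_coefficients) +
    coupling.T`` and must have spectral radius < 1.
    """

    node_labels: list[str]
    self_coefficients: np.ndarray
    coupling: np.ndarray
    innovation_sd: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        self.self_coefficients = np.asarray(self.self_coefficients, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.innovation_sd = np.broadcast_to(
            np.asarray(self.innovation_sd, dtype=float), (n,)
        ).copy()
        if self.self_coefficients.shape != (n,):
            raise ValueError("need one self coefficient per node")
        if self.coupling.shape != (n, n):
            raise ValueError("coupling must be an (n, n) matrix")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")
        if np.any(self.innovation_sd < 0):
            raise ValueError("innovation SDs must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def transition_matrix(self) -> np.ndarray:
        """Lag-1 companion matrix mapping x_{t-1} to E[x_t]."""
        return np.diag(self.self_coefficients) + self.coupling.T

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.transition_matrix()))))

    def validate_stationary(self) -> None:
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(
                f"non-stationary network: companion spectral radius {rho:.4f} >= 1"
            )

    def with_coupling(self, coupling: np.ndarray) -> "NetworkSpec":
        return NetworkSpec(
            self.node_labels, self.self_coefficients.copy(), coupling,
            self.innovation_sd.copy(),
        )

    def index(self, label: str) -> int:
        return self.node_labels.index(label)


@dataclass
class ScoreModel:
    """Linear map from a subject's realized coupling to a clinical score.

    ``score = intercept + slope * coupling[edge] + Normal(0, noise_sd)``.
    """

    edge: tuple[str, str] = ("itg", "seed_r")
    intercept: float = 40.0
    slope: float = -60.0
    noise_sd: float = 2.0


@dataclass
class CohortConfig:
    """Study-scale settings for a synthetic cohort.

    Defaults mirror the study conditions: 22 patients vs 21 controls,
    205 volumes at TR = 2 s (5 later discarded), with a desk-scale
    24 x 24 x 12 voxel grid standing in for the acquisition matrix.
    """

    n_group_a: int = 22
    n_group_b: int = 21
    group_labels: tuple[str, str] = ("SAD", "HC")
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    n_volumes: int = 205
    tr_seconds: float = 2.0
    region_layout: dict[str, Block] = field(default_factory=lambda: dict(DEFAULT_LAYOUT))
    group_b_coupling_delta: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("itg", "seed_r"): 0.3, ("seed_l", "visual"): -0.15}
    )
    coupling_jitter_sd: float = 0.10
    score_model: ScoreModel = field(default_factory=ScoreModel)
    observation_noise_sd: float = 0.5
    drift_amplitude: float = 0.3
    motion_leak: float = 0.2
    motion_step_sd_mm: float = 0.02
    motion_step_sd_deg: float = 0.02
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed 10")
        _check_layout(self.region_layout, self.grid_dims)


#: Default spatial layout (blocks as ((x0,x1),(y0,y1),(z0,z1)), end-exclusive)
#: on the 24 x 24 x 12 grid: two seed regions, a temporal-like and a
#: visual-like target region, plus WM and CSF nuisance compartments.
DEFAULT_LAYOUT: dict[str, Block] = {
    "seed_l": ((3, 6), (9, 12), (4, 7)),
    "seed_r": ((18, 21), (9, 12), (4, 7)),
    "itg": ((4, 8), (16, 20), (2, 5)),
    "visual": ((10, 14), (19, 23), (5, 8)),
    "wm": ((9, 13), (3, 7), (3, 7)),
    "csf": ((10, 13), (10, 13), (8, 11)),
}

#: Node labels that carry VAR network signals (the rest are nuisance).
NETWORK_NODES = ("seed_l", "seed_r", "itg", "visual")
NUISANCE_NODES = ("wm", "csf")


def default_network() -> NetworkSpec:
    """Baseline (group A / patient) network.

    Weak inferior-temporal -> right-seed influence (strengthened in
    controls via the group delta) and a reciprocal left-seed <-> visual
    loop (weakened in controls), on top of AR(1) self terms of 0.5.
    """
    labels = list(NETWORK_NODES)
    n = len(labels)
    coupling = np.zeros((n, n))

    def edge(src: str, dst: str, w: float) -> None:
        coupling[labels.index(src), labels.index(dst)] = w

    edge("itg", "seed_r", 0.25)
    edge("seed_l", "visual", 0.45)
    edge("visual", "seed_l", 0.20)
    spec = NetworkSpec(labels, np.full(n, 0.5), coupling, np.ones(n))
    spec.validate_stationary()
    return spec


def default_cohort_config(**overrides) -> CohortConfig:
    cfg = CohortConfig(**overrides)
    cfg.validate()
    return cfg


def _check_layout(layout: dict[str, Block], grid: tuple[int, int, int]) -> None:
    occupancy = np.zeros(grid, dtype=int)
    for name, block in layout.items():
        sl = tuple(slice(a, b) for a, b in block)
        for (a, b), dim in zip(block, grid):
            if not (0 <= a < b <= dim):
                raise ValueError(f"region '{name}' block {block} outside grid {grid}")
        occupancy[sl] += 1
    if np.any(occupancy > 1):
        raise ValueError("region blocks overlap")


def simulate_coupled_var(
    spec: NetworkSpec, n_volumes: int, rng_seed: int | np.random.Generator = 0
) -> dict[str, np.ndarray]:
    """Realize the network as one series per node of length ``n_volumes``.

    The lag-1 recursion ``x_t = A x_{t-1} + eps_t`` with independent
    Gaussian innovations is iterated from zero; a 200-sample burn-in is
    discarded so the output is (approximately) a draw from the stationary
    distribution.  Identical seeds give identical output.
    """
    spec.validate_stationary()
    if n_volumes < 20:
        raise ValueError("n_volumes must be at least 20")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    a_mat = spec.transition_matrix()
    n = spec.n_nodes
    total = n_volumes + BURN_IN
    innov = rng.standard_normal((total, n)) * spec.innovation_sd
    series = np.zeros((total, n))
    prev = np.zeros(n)
    for t in range(total):
        prev = a_mat @ prev + innov[t]
        series[t] = prev
    series = series[BURN_IN:]
    return {label: series[:, i].copy() for i, label in enumerate(spec.node_labels)}


def build_phantom(
    series_set: dict[str, np.ndarray],
    config: CohortConfig,
    observation_noise_sd: float | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    """Embed node series into a 4-D volume with aligned masks.

    Every voxel of node i's block carries node i's series plus i.i.d.
    Gaussian observation noise; WM/CSF blocks carry their (independent)
    nuisance series; all remaining voxels are pure noise.  Returns
    ``(volume, roi_masks, brain_mask, wm_mask, csf_mask)``; the brain
    mask covers the whole grid.
    """
    _check_layout(config.region_layout, config.grid_dims)
    noise_sd = (
        config.observation_noise_sd if observation_noise_sd is None else observation_noise_sd
    )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lengths = {len(s) for s in series_set.values()}
    if len(lengths) != 1:
        raise ValueError("all node series must share one length")
    n_t = lengths.pop()
    grid = config.grid_dims
    base_sd = noise_sd if noise_sd > 0 else 1.0
    volume = rng.standard_normal(grid + (n_t,)) * base_sd

    roi_masks: dict[str, np.ndarray] = {}
    for name, block in config.region_layout.items():
        if name not in series_set:
            raise ValueError(f"no series provided for region '{name}'")
        sl = tuple(slice(a, b) for a, b in block)
        mask = np.zeros(grid, dtype=bool)
        mask[sl] = True
        roi_masks[name] = mask
        if noise_sd > 0:
            volume[sl] = series_set[name] + rng.standard_normal(
                volume[sl].shape
            ) * noise_sd
        else:
            volume[sl] = series_set[name]

    brain_mask = np.ones(grid, dtype=bool)
    wm_mask = roi_masks.get("wm", np.zeros(grid, dtype=bool))
    csf_mask = roi_masks.get("csf", np.zeros(grid, dtype=bool))
    return volume, roi_masks, brain_mask, wm_mask, csf_mask


def simulate_motion_trace(
    n_volumes: int,
    step_sd_mm: float = 0.02,
    step_sd_deg: float = 0.02,
    spike: tuple[int, float] | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> MotionTrace:
    """Cumulative random-walk motion trace (3 translations mm, 3 rotations deg).

    ``spike`` optionally injects an abrupt displacement of the given
    magnitude at the given volume on the first translation axis, for
    exercising the exclusion rule.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    trans = np.cumsum(rng.standard_normal((n_volumes, 3)) * step_sd_mm, axis=0)
    rot = np.cumsum(rng.standard_normal((n_volumes, 3)) * step_sd_deg, axis=0)
    if spike is not None:
        idx, magnitude = spike
        trans[int(idx):, 0] += magnitude
    return MotionTrace(trans, rot)


@dataclass
class SubjectData:
    """One synthetic subject: volume, motion, realized couplings, record."""

    record: SubjectRecord
    volume: np.ndarray  # float32 (X, Y, Z, T)
    motion: MotionTrace
    coupling: np.ndarray


@dataclass
class Cohort:
    """A full synthetic dataset plus its shared masks and configuration."""

    config: CohortConfig
    spec_group_a: NetworkSpec
    spec_group_b: NetworkSpec
    subjects: list[SubjectData]
    roi_masks: dict[str, np.ndarray]
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray

    def records_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s.record) for s in self.subjects])


#: Group-wise distributions (mean, sd) used for the free clinical scores,
#: matching the study-scale behavioral table; the avoidance score is
#: instead generated from the score model, and the total is fear + avoidance.
SCORE_DISTRIBUTIONS = {
    "SAD": {
        "age": (22.55, 4.04),
        "education": (13.91, 1.44),
        "lsas_fear": (26.55, 4.82),
        "hamd": (8.45, 6.00),
        "hama": (6.32, 4.42),
        "stai_t": (46.77, 7.86),
        "stai_s_pre": (40.95, 8.38),
        "stai_s_post": (38.14, 9.54),
        "p_male": 16 / 22,
    },
    "HC": {
        "age": (21.71, 3.64),
        "education": (14.0, 1.92),
        "lsas_fear": (8.76, 4.97),
        "hamd": (1.29, 1.82),
        "hama": (1.24, 1.81),
        "stai_t": (33.29, 5.12),
        "stai_s_pre": (31.48, 4.74),
        "stai_s_post": (33.14, 6.90),
        "p_male": 15 / 21,
    },
}


def _apply_delta(
    spec: NetworkSpec, delta: dict[tuple[str, str], float]
) -> NetworkSpec:
    coupling = spec.coupling.copy()
    for (src, dst), dv in delta.items():
        coupling[spec.index(src), spec.index(dst)] += dv
    out = spec.with_coupling(coupling)
    out.validate_stationary()
    return out


def _jitter_coupling(
    spec: NetworkSpec, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Perturb the nonzero edges; shrink toward the mean if stationarity breaks."""
    coupling = spec.coupling.copy()
    nz = coupling != 0
    coupling[nz] += rng.standard_normal(np.count_nonzero(nz)) * jitter_sd
    for _ in range(10):
        cand = spec.with_coupling(coupling)
        if cand.spectral_radius() < 0.999:
            return coupling
        coupling = spec.coupling + 0.5 * (coupling - spec.coupling)
    return spec.coupling.copy()


def synthesize_cohort(
    config: CohortConfig | None = None, spec: NetworkSpec | None = None
) -> Cohort:
    """Generate the full two-group synthetic dataset.

    Group B subjects use ``coupling + group_b_coupling_delta``; every
    subject's couplings are additionally jittered (Gaussian,
    ``coupling_jitter_sd``) around the group mean.  The avoidance score is
    the score model applied to the subject's realized target-edge
    coupling plus noise; the remaining clinical scores are drawn from the
    group-wise distributions above.  Linear drift and a motion-correlated
    component are added to every in-brain voxel so the preprocessing
    stages have real work to do.
    """
    config = config or default_cohort_config()
    spec = spec or default_network()
    config.validate()
    spec.validate_stationary()
    sm = config.score_model
    if sm.slope == 0 and sm.noise_sd == 0:
        warnings.warn("degenerate score model: zero slope and zero noise", stacklevel=2)

    spec_b = _apply_delta(spec, config.group_b_coupling_delta)
    n_total = config.n_group_a + config.n_group_b
    seed_seq = np.random.SeedSequence(config.rng_seed)
    children = seed_seq.spawn(n_total)

    subjects: list[SubjectData] = []
    shared_masks = None
    edge_idx = (spec.index(sm.edge[0]), spec.index(sm.edge[1]))
    for i in range(n_total):
        in_group_a = i < config.n_group_a
        group = config.group_labels[0] if in_group_a else config.group_labels[1]
        base = spec if in_group_a else spec_b
        rng = np.random.default_rng(children[i])

        coupling_i = _jitter_coupling(base, config.coupling_jitter_sd, rng)
        spec_i = base.with_coupling(coupling_i)
        node_series = simulate_coupled_var(spec_i, config.n_volumes, rng)
        # independent nuisance compartments (slow AR(1) signals)
        for name in NUISANCE_NODES:
            if name in config.region_layout:
                nspec = NetworkSpec([name], np.array([0.8]), np.zeros((1, 1)), np.ones(1))
                node_series[name] = simulate_coupled_var(
                    nspec, config.n_volumes, rng
                )[name]

        motion = simulate_motion_trace(
            config.n_volumes, config.motion_step_sd_mm, config.motion_step_sd_deg,
            rng_seed=rng,
        )
        volume, roi_masks, brain_mask, wm_mask, csf_mask = build_phantom(
            node_series, config, rng_seed=rng
        )
        # nuisance structure on top of the clean phantom: linear drift and a
        # component tracking the first translation parameter
        t_axis = np.linspace(-0.5, 0.5, config.n_volumes)
        drift = config.drift_amplitude * rng.standard_normal(config.grid_dims)
        volume += drift[..., None] * t_axis
        mot = motion.translations[:, 0]
        mot_sd = mot.std()
        if config.motion_leak > 0 and mot_sd > 0:
            volume += config.motion_leak * ((mot - mot.mean()) / mot_sd)

        score = sm.intercept + sm.slope * coupling_i[edge_idx] + rng.normal(
            0.0, sm.noise_sd
        )
        dist = SCORE_DISTRIBUTIONS[group]
        fear = rng.normal(*dist["lsas_fear"])
        record = SubjectRecord(
            subject_id=f"sub-{i + 1:02d}",
            group=group,
            lsas_total=fear + score,
            lsas_fear=fear,
            lsas_avoidance=score,
            hamd=rng.normal(*dist["hamd"]),
            hama=rng.normal(*dist["hama"]),
            stai_t=rng.normal(*dist["stai_t"]),
            stai_s_pre=rng.normal(*dist["stai_s_pre"]),
            stai_s_post=rng.normal(*dist["stai_s_post"]),
            sex="male" if rng.random() < dist["p_male"] else "female",
            age=rng.normal(*dist["age"]),
            education=rng.normal(*dist["education"]),
        )
        subjects.append(
            SubjectData(
                record=record,
                volume=volume.astype(np.float32),
                motion=motion,
                coupling=coupling_i,
            )
        )
        if shared_masks is None:
            shared_masks = (roi_masks, brain_mask, wm_mask, csf_mask)

    roi_masks, brain_mask, wm_mask, csf_mask = shared_masks
    return Cohort(
        config=config,
        spec_group_a=spec,
        spec_group_b=spec_b,
        subjects=subjects,
        roi_masks=roi_masks,
        brain_mask=brain_mask,
        wm_mask=wm_mask,
        csf_mask=csf_mask,
    )
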