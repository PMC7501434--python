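"""Synthetic cohort generation.

Ground truth is expressed directly in the quantity the pipeline estimates:
per-(group, condition) matrices of partial correlations, converted to
precision matrices of a zero-mean multivariate Gaussian. Node time series
are i.i.d. Gaussian frames drawn from the implied covariance, with
per-node standard deviations (the SDSA ground truth) applied as a diagonal
scaling that leaves partial correlations untouched. An optional AR(1)
coefficient adds temporal smoothness for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUPS = ("patient", "control")
CONDITIONS = ("rest", "L1", "L2")
DEFAULT_FRAMES = {"rest": 200, "L1": 152, "L2": 152}


@dataclass
class EffectSpec:
    """Edge- and node-level effects injected into the ground truth.

    Node indices are 1-based with ``i < j``. ``condition_edges`` set the
    partial correlation of an edge per condition (identically in both
    groups); ``group_edges`` add a patient-minus-control offset to an
    edge's partial correlation per condition; ``sdsa_nodes`` multiply a
    node's time-series standard deviation per condition (both groups).
    """

    condition_edges: list[tuple[int, int, dict[str, float]]] = field(default_factory=list)
    group_edges: list[tuple[int, int, dict[str, float]]] = field(default_factory=list)
    sdsa_nodes: list[tuple[int, dict[str, float]]] = field(default_factory=list)


@dataclass
class GroundTruthModel:
    """Per-cell precision matrices and node scales defining the generator."""

    n_nodes: int
    precision: dict[tuple[str, str], np.ndarray]
    node_scale: dict[tuple[str, str], np.ndarray]
    group_effect_edges: list[tuple[int, int, dict[str, float]]]
    condition_effect_edges: list[tuple[int, int, dict[str, float]]]
    groups: tuple[str, ...] = GROUPS
    conditions: tuple[str, ...] = CONDITIONS

    def covariance(self, group: str, condition: str) -> np.ndarray:
        """Model covariance: scaled inverse precision.

        The precision matrix describes the standardized process; node
        scales enter as an outer diagonal scaling, so partial correlations
        are independent of the SDSA ground truth.
        """
        theta = self.precision[(group, condition)]
        sigma = np.linalg.inv(theta)
        d = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(d, d)
        s = self.node_scale[(group, condition)]
        return corr * np.outer(s, s)

    def partial_correlations(self, group: str, condition: str) -> np.ndarray:
        theta = self.precision[(group, condition)]
        d = np.sqrt(np.diag(theta))
        p = -theta / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
        return p


@dataclass
class Subject:
    id: str
    group: str


@dataclass
class CohortTimeSeries:
    """Per subject × condition node time series with group labels."""

    subjects: list[Subject]
    series: dict[tuple[str, str], np.ndarray]
    frames_per_condition: dict[str, int]
    n_nodes: int
    seed: int | None = None

    def groups_of(self) -> dict[str, str]:
        return {s.id: s.group for s in self.subjects}


@dataclass
class ToyVolumeSet:
    """Small synthetic 4D datasets (voxels unrolled) for dual regression."""

    maps: np.ndarray                      # V x K spatial maps
    lesion_mask: np.ndarray               # V binary
    volumes: dict[tuple[str, str], np.ndarray]        # (subject, condition) -> V x T
    lesion_signal: dict[tuple[str, str], np.ndarray]  # T-vector per lesioned run
    cohort: CohortTimeSeries


def default_effect_spec(
    n_nodes: int = 30,
    n_condition_edges: int = 20,
    condition_delta: tuple[float, float] = (0.1, 0.3),
    group_edge: tuple[int, int] | None = None,
    group_delta: float = 0.1,
    n_sdsa_nodes: int = 4,
    sdsa_task_factor: float = 0.8,
    seed: int = 0,
) -> EffectSpec:
    """Build the default effect specification.

    Defaults emulate the qualitative structure of a rest-vs-tracking
    stroke study: ~20 edges modulated by condition with |Δρ| in
    [0.1, 0.3], one edge carrying a constant patient–control offset of
    0.1 (the temporal–sensorimotor analog), and a 20% task-related
    decrease of signal SD on 4 "task-negative" nodes.
    """
    rng = np.random.default_rng(seed)
    pairs = [(i, j) for i in range(1, n_nodes + 1) for j in range(i + 1, n_nodes + 1)]
    # cap effect density on small graphs so the model stays positive definite
    n_condition_edges = min(n_condition_edges, max(1, len(pairs) // 5))
    if group_edge is None:
        # analog of the temporal(23)-sensorimotor(27) edge when K allows
        group_edge = (23, 27) if n_nodes >= 27 else (n_nodes - 2, n_nodes)
    chosen = rng.choice(len(pairs), size=min(n_condition_edges + 1, len(pairs)), replace=False)
    cond_edges = []
    for idx in chosen:
        i, j = pairs[idx]
        if (i, j) == tuple(group_edge):
            continue
        if len(cond_edges) == n_condition_edges:
            break
        base = rng.uniform(0.05, 0.15) * rng.choice([-1.0, 1.0])
        delta = rng.uniform(*condition_delta)
        # monotone load modulation: rest -> L1 -> L2
        cond_edges.append((i, j, {"rest": base, "L1": base + delta / 2, "L2": base + delta}))
    group_edges = []
    if group_delta != 0.0 and group_edge is not None:
        group_edges = [(group_edge[0], group_edge[1], {c: group_delta for c in CONDITIONS})]
    nodes = rng.choice(np.arange(1, n_nodes + 1), size=min(n_sdsa_nodes, n_nodes), replace=False)
    sdsa_nodes = [(int(n), {"rest": 1.0, "L1": sdsa_task_factor, "L2": sdsa_task_factor}) for n in nodes]
    return EffectSpec(condition_edges=cond_edges, group_edges=group_edges, sdsa_nodes=sdsa_nodes)


def _check_edge_indices(edges, n_nodes):
    for e in edges:
        i, j = e[0], e[1]
        if not (1 <= i < j <= n_nodes):
            raise ValueError(f"edge ({i},{j}) out of range for {n_nodes} nodes (need 1 <= i < j <= K)")


def make_ground_truth(
    n_nodes: int = 30,
    sparsity: float = 0.1,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
    base_rho: tuple[float, float] = (0.1, 0.3),
    min_eig: float = 0.1,
) -> GroundTruthModel:
    """Construct per-(group, condition) precision matrices.

    Target partial correlations are placed on a random background graph
    (edge probability ``sparsity``) plus the requested effect edges. Each
    cell's precision is Θ = c·(I − P_off) with P_off holding the target
    partial correlations off-diagonal and c a uniform diagonal loading
    factor chosen so the smallest eigenvalue is at least ``min_eig``;
    uniform loading leaves −Θij/√(ΘiiΘjj) equal to the targets exactly.
    Background magnitudes are shrunk (identically in every cell, so no
    spurious effects arise) if needed for positive definiteness; effect
    edges are never altered — an unrealizable request raises instead.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    if effect_spec is None:
        effect_spec = default_effect_spec(n_nodes, seed=seed)
    _check_edge_indices(effect_spec.condition_edges, n_nodes)
    _check_edge_indices(effect_spec.group_edges, n_nodes)

    rng = np.random.default_rng(seed)
    K = n_nodes
    iu = np.triu_indices(K, 1)
    effect_pairs = {(i - 1, j - 1) for i, j, _ in effect_spec.condition_edges}
    effect_pairs |= {(i - 1, j - 1) for i, j, _ in effect_spec.group_edges}

    base = np.zeros((K, K))
    mask = rng.random(len(iu[0])) < sparsity
    vals = rng.uniform(*base_rho, size=len(iu[0])) * rng.choice([-1.0, 1.0], size=len(iu[0]))
    base[iu] = np.where(mask, vals, 0.0)
    for i, j in effect_pairs:
        base[i, j] = 0.0  # effect edges are set explicitly per cell
    base = base + base.T

    def cell_partial(group: str, cond: str, shrink: float) -> np.ndarray:
        P = base * shrink
        for i, j, by_cond in effect_spec.condition_edges:
            P[i - 1, j - 1] = P[j - 1, i - 1] = by_cond[cond]
        for i, j, by_cond in effect_spec.group_edges:
            off = by_cond[cond] if group == "patient" else 0.0
            P[i - 1, j - 1] = P[j - 1, i - 1] = P[i - 1, j - 1] + off
        return P

    # one background shrink factor shared by every cell (P has zero diagonal)
    shrink = 1.0
    for _ in range(60):
        ok = all(
            np.linalg.eigvalsh(np.eye(K) - cell_partial(g, c, shrink))[0] > 1e-8
            for g in GROUPS
            for c in CONDITIONS
        )
        if ok:
            break
        shrink *= 0.85
    else:
        shrink = 0.0

    precision: dict[tuple[str, str], np.ndarray] = {}
    for g in GROUPS:
        for c in CONDITIONS:
            P = cell_partial(g, c, shrink)
            M = np.eye(K) - P
            w = np.linalg.eigvalsh(M)[0]
            if w <= 1e-8:
                ii, jj = np.unravel_index(np.argmax(np.abs(P - np.diag(np.diag(P)))), P.shape)
                raise ValueError(
                    f"requested effects cannot be realized as a positive-definite model: "
                    f"edge ({min(ii, jj) + 1},{max(ii, jj) + 1}) with partial correlation "
                    f"{P[ii, jj]:.3f} in cell ({g}, {c})"
                )
            cfac = max(1.0, min_eig / w)
            precision[(g, c)] = cfac * M

    node_scale: dict[tuple[str, str], np.ndarray] = {}
    for g in GROUPS:
        for c in CONDITIONS:
            s = np.ones(K)
            for node, by_cond in effect_spec.sdsa_nodes:
                s[node - 1] = by_cond[c]
            if np.any(s <= 0):
                raise ValueError("node scales must be strictly positive")
            node_scale[(g, c)] = s

    return GroundTruthModel(
        n_nodes=K,
        precision=precision,
        node_scale=node_scale,
        group_effect_edges=list(effect_spec.group_edges),
        condition_effect_edges=list(effect_spec.condition_edges),
    )


def sample_timeseries(
    model: GroundTruthModel,
    group: str,
    condition: str,
    T: int,
    seed: int = 0,
    ar_coef: float = 0.0,
) -> np.ndarray:
    """Draw a T×K run from the model's (group, condition) covariance.

    Frames are i.i.d. by default; ``ar_coef`` in (0, 1) applies an AR(1)
    filter across frames (variance-preserving) as an optional realism knob.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    cov = model.covariance(group, condition)
    w = np.linalg.eigvalsh(cov)[0]
    if w <= 0:
        raise ValueError("model covariance is not positive definite")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((T, model.n_nodes)) @ L.T
    if ar_coef:
        if not 0 < ar_coef < 1:
            raise ValueError("ar_coef must be in (0, 1)")
        innov_sd = np.sqrt(1.0 - ar_coef**2)
        Y = np.empty_like(X)
        Y[0] = X[0]
        for t in range(1, T):
            Y[t] = ar_coef * Y[t - 1] + innov_sd * X[t]
        X = Y
    return X


def generate_cohort(
    model: GroundTruthModel,
    n_patients: int = 44,
    n_controls: int = 100,
    frames: dict[str, int] | None = None,
    seed: int = 0,
    ar_coef: float = 0.0,
) -> CohortTimeSeries:
    """Sample a full cohort: every subject gets all three conditions.

    Deterministic given ``seed``: per-run seeds are spawned from a single
    seed sequence in a fixed subject/condition order.
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    frames = dict(DEFAULT_FRAMES if frames is None else frames)
    subjects = [Subject(f"sub-P{i + 1:03d}", "patient") for i in range(n_patients)]
    subjects += [Subject(f"sub-C{i + 1:03d}", "control") for i in range(n_controls)]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(subjects) * len(model.conditions))
    series: dict[tuple[str, str], np.ndarray] = {}
    k = 0
    for sub in subjects:
        for cond in model.conditions:
            run_seed = children[k]
            k += 1
            series[(sub.id, cond)] = sample_timeseries(
                model, sub.group, cond, frames[cond], seed=run_seed, ar_coef=ar_coef
            )
    return CohortTimeSeries(
        subjects=subjects,
        series=series,
        frames_per_condition=frames,
        n_nodes=model.n_nodes,
        seed=seed,
    )


def make_toy_volumes(
    maps: np.ndarray,
    cohort: CohortTimeSeries,
    lesion_spec: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ToyVolumeSet:
    """Build small voxel-by-time datasets: volumes = maps·seriesᵀ + lesion + noise.

    ``lesion_spec`` is ``{"mask": V-binary-vector, "amplitude": float}``;
    the lesion signal (Gaussian, SD = amplitude) is injected only into
    masked voxels and only for patient subjects.
    """
    maps = np.asarray(maps, dtype=float)
    V, K = maps.shape
    if K != cohort.n_nodes:
        raise ValueError(f"maps have {K} columns but cohort has {cohort.n_nodes} nodes")
    if np.linalg.matrix_rank(maps) < K:
        raise ValueError("spatial maps are rank deficient")
    if lesion_spec is not None:
        lesion_mask = np.asarray(lesion_spec["mask"], dtype=float)
        if lesion_mask.shape != (V,) or not np.isin(lesion_mask, [0.0, 1.0]).all():
            raise ValueError("lesion mask must be a binary V-vector")
        amplitude = float(lesion_spec.get("amplitude", 0.0))
    else:
        lesion_mask = np.zeros(V)
        amplitude = 0.0
    if V < K + 1:
        raise ValueError("need V >= K+1 voxels")

    rng = np.random.default_rng(seed)
    groups = cohort.groups_of()
    volumes: dict[tuple[str, str], np.ndarray] = {}
    lesion_signal: dict[tuple[str, str], np.ndarray] = {}
    for (sid, cond), ts in cohort.series.items():
        vol = maps @ ts.T
        if amplitude != 0.0 and groups[sid] == "patient":
            sig = rng.standard_normal(ts.shape[0]) * amplitude
            vol = vol + np.outer(lesion_mask, sig)
            lesion_signal[(sid, cond)] = sig
        if noise_sd > 0:
            vol = vol + rng.standard_normal(vol.shape) * noise_sd
        volumes[(sid, cond)] = vol
    return ToyVolumeSet(
        maps=maps,
        lesion_mask=lesion_mask,
        volumes=volumes,
        lesion_signal=lesion_signal,
        cohort=cohort,
    )


def random_maps(n_voxels: int, n_nodes: int, seed: int = 0, smooth: int = 0) -> np.ndarray:
    """Random full-rank spatial maps for toy volumes (Gaussian weights)."""
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n_voxels, n_nodes))
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        M = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 0, M)
    return M
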