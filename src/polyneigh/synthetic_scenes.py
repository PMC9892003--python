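"""Synthetic ribosome particle fields with known polysome ground truth.

Each synthetic tomogram contains one spherical ER-derived vesicle carrying
membrane-bound ribosomes (particle-frame z along the outward membrane
normal, so the membrane lies in the particle's xy plane) plus residual
soluble ribosomes.  Polysome chains are grown by stepping along the vesicle
surface with a fixed trailing-offset vector expressed in the current
particle's frame; each successive ribosome's in-plane azimuth is set so
that its leading neighbor sits at the configured leading offset, mimicking
the characteristic trailing/leading neighbor hotspots of real polysomes.
Soluble ribosomes form free 3D chains with the same offsets.  Per-tomogram
polysome propensity varies on the logit scale (the random effect the
association model is built to absorb), and Gaussian positional/angular
jitter is applied last, after ground truth is recorded.

The offsets, densities and state catalog are synthetic stand-ins chosen to
be geometrically plausible (offset magnitudes within the 100 A neighbor
cutoff, a 50 A hard-core separation approximating ribosome excluded
volume); they are configuration, not measured values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special

from .particle_io import ParticleTable, POPULATION_VOCAB
from .rigid_geometry import rotation_to_euler

__all__ = [
    "StateSpec",
    "SceneConfig",
    "SceneTruth",
    "generate_scene",
    "generate_association_dataset",
    "DEFAULT_STATE_CATALOG",
]


@dataclasses.dataclass(frozen=True)
class StateSpec:
    """One ribosome state: overall abundance and polysome propensity."""

    label: str
    base_probability: float
    in_polysome_probability: float


#: Elongation-cycle intermediates are frequent polysome members; the two
#: hibernating states (NR-H, R-H) are essentially absent from polysomes.
#: Base abundances follow the rough proportions seen in ER-vesicle data.
DEFAULT_STATE_CATALOG = (
    StateSpec("decoding", 0.22, 0.70),
    StateSpec("pre+", 0.33, 0.70),
    StateSpec("pre", 0.03, 0.70),
    StateSpec("rotated-1", 0.04, 0.70),
    StateSpec("rotated-2", 0.17, 0.70),
    StateSpec("translocation", 0.05, 0.70),
    StateSpec("post", 0.04, 0.70),
    StateSpec("NR-H", 0.07, 0.03),
    StateSpec("R-H", 0.05, 0.03),
)

#: Translocon-population weights for membrane-bound chains/monosomes.
_MEMBRANE_POPULATIONS = (
    ("SEC61-TRAP-OSTA", 0.69),
    ("SEC61-TRAP", 0.10),
    ("multipass", 0.12),
    ("multipass-TRAP", 0.09),
)


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    """Scene parameters (lengths in Angstrom, angles in degrees)."""

    n_tomograms: int = 20
    seed: int = 0
    vesicle_radius: float = 1000.0
    membrane_density: float = 1200.0  # particles per um^2 of membrane
    soluble_fraction: float = 0.2  # fraction of all particles that are soluble
    state_catalog: tuple[StateSpec, ...] = DEFAULT_STATE_CATALOG
    trailing_offset: tuple[float, float, float] = (45.0, 30.0, 0.0)
    leading_offset: tuple[float, float, float] = (-45.0, -30.0, 0.0)
    positional_jitter_sd: float = 5.0
    angular_jitter_sd: float = 3.0
    tomogram_effect_sd: float = 0.5
    min_separation: float = 50.0

    def __post_init__(self):
        total = sum(s.base_probability for s in self.state_catalog)
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"state base probabilities sum to {total}, not 1")
        for off in (self.trailing_offset, self.leading_offset):
            mag = float(np.linalg.norm(off))
            if mag > 100.0:
                raise ValueError(f"offset magnitude {mag:.1f} A exceeds 100 A cutoff")
            if mag <= self.min_separation:
                raise ValueError("offset magnitude must exceed min_separation")
        t = np.linalg.norm(self.trailing_offset)
        l = np.linalg.norm(self.leading_offset)
        if abs(t - l) > 1e-6:
            raise ValueError(
                "trailing and leading offsets must share magnitude "
                "(the same inter-particle distance seen from both ends)"
            )


@dataclasses.dataclass
class SceneTruth:
    """Pre-jitter ground truth for recovery tests."""

    true_edges: set[tuple[str, int, int]]  # (tomogram_id, trailing_id, leading_id)
    true_membership: dict[tuple[str, int], bool]
    per_tomogram_effects: dict[str, float]
    frame_normals: dict[tuple[str, int], np.ndarray]


def _rot_z_mat(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _normal_frame(normal: np.ndarray, azimuth_rad: float) -> np.ndarray:
    """Rotation mapping tomogram frame -> particle frame with z along ``normal``.

    The particle-frame x axis points along an azimuth-rotated tangent.
    """
    n = normal / np.linalg.norm(normal)
    helper = np.array([0.0, 0.0, 1.0]) if abs(n[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, n)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    base = np.vstack([e1, e2, n])  # rows: maps tomogram vec to frame coords
    return _rot_z_mat(azimuth_rad) @ base


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from normalized quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _small_rotation(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    """Small random rotation with per-axis rotation-vector sd ``sd_deg``."""
    if sd_deg == 0.0:
        return np.eye(3)
    v = np.radians(rng.normal(0.0, sd_deg, size=3))
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        return np.eye(3)
    k = v / angle
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


class _TomogramBuilder:
    """Accumulates particles of one tomogram with hard-core rejection."""

    def __init__(self, tomogram_id: str, center: np.ndarray, min_sep: float):
        self.tomogram_id = tomogram_id
        self.center = center
        self.min_sep = min_sep
        self.positions: list[np.ndarray] = []
        self.rotations: list[np.ndarray] = []
        self.states: list[str] = []
        self.populations: list[str] = []

    def clear_of(self, pos: np.ndarray) -> bool:
        if not self.positions:
            return True
        arr = np.asarray(self.positions)
        d = np.linalg.norm(arr - pos, axis=1)
        return bool(np.all(d >= self.min_sep))

    def add(self, pos, rot, state, population) -> int:
        self.positions.append(np.asarray(pos, float))
        self.rotations.append(np.asarray(rot, float))
        self.states.append(state)
        self.populations.append(population)
        return len(self.positions) - 1


def _sample_sphere_point(rng, center, radius):
    v = rng.normal(size=3)
    n = v / np.linalg.norm(v)
    return center + radius * n, n


def generate_scene(config: SceneConfig = SceneConfig()) -> tuple[ParticleTable, SceneTruth]:
    """Generate a particle table plus pre-jitter ground truth.

    Fixed seed gives a byte-identical table; each tomogram draws from its
    own random substream so scene statistics do not depend on tomogram
    order.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(config.n_tomograms)]
    r = config.vesicle_radius
    area_um2 = 4.0 * np.pi * (r * 1e-4) ** 2
    base_p = np.array([s.base_probability for s in config.state_catalog])
    poly_p = np.array([s.in_polysome_probability for s in config.state_catalog])
    labels = [s.label for s in config.state_catalog]
    pop_labels = [p for p, _ in _MEMBRANE_POPULATIONS]
    pop_w = np.array([w for _, w in _MEMBRANE_POPULATIONS])
    pop_w = pop_w / pop_w.sum()
    t_off = np.asarray(config.trailing_offset, float)
    l_off = np.asarray(config.leading_offset, float)
    phi_lead = np.arctan2(l_off[1], l_off[0])

    frames = []
    truth = SceneTruth(set(), {}, {}, {})

    for t in range(config.n_tomograms):
        rng = streams[t]
        tid = f"tomo_{t:04d}"
        u_t = float(rng.normal(0.0, config.tomogram_effect_sd))
        truth.per_tomogram_effects[tid] = u_t
        center = np.full(3, 2.5 * r) + rng.uniform(-0.2 * r, 0.2 * r, size=3)
        builder = _TomogramBuilder(tid, center, config.min_separation)
        cont_p = special.expit(special.logit(np.clip(poly_p, 1e-12, 1 - 1e-12)) + u_t)
        cont_p = np.where(poly_p <= 0.0, 0.0, np.where(poly_p >= 1.0, 1.0, cont_p))
        # states inside chains are abundance-reweighted by polysome propensity,
        # monosome states by its complement, keeping marginals near base_p
        w_chain = base_p * cont_p
        w_chain = w_chain / w_chain.sum() if w_chain.sum() > 0 else base_p
        w_mono = base_p * (1.0 - cont_p)
        w_mono = w_mono / w_mono.sum() if w_mono.sum() > 0 else base_p

        n_membrane = int(rng.poisson(config.membrane_density * area_um2))
        _fill_membrane(
            builder, rng, config, center, n_membrane, base_p, cont_p,
            w_chain, w_mono, labels, pop_labels, pop_w, t_off, l_off,
            phi_lead, truth,
        )
        n_soluble = int(
            rng.poisson(
                n_membrane * config.soluble_fraction / max(1e-9, 1 - config.soluble_fraction)
            )
        )
        _fill_soluble(
            builder, rng, config, center, n_soluble, base_p, cont_p,
            w_chain, w_mono, labels, t_off, l_off, truth,
        )
        frames.append(_finalize(builder, rng, config, truth))

    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table = ParticleTable(
        df, pixel_size=1.0,
        provenance=f"synthetic scene, seed={config.seed}",
    )
    return table, truth


def _draw_chain_length(rng, c: float) -> int:
    """1 (monosome) with prob 1-c, else 2 + Geometric(1-c) - 1 members."""
    if c <= 0.0 or rng.random() >= c:
        return 1
    if c >= 1.0:
        c = 1.0 - 1e-12
    return 1 + int(rng.geometric(1.0 - c))


def _fill_membrane(builder, rng, config, center, n_target, base_p, cont_p,
                   w_chain, w_mono, labels, pop_labels, pop_w, t_off, l_off,
                   phi_lead, truth):
    r = config.vesicle_radius
    placed = 0
    failures = 0
    while placed < n_target:
        if failures > 10_000:
            raise RuntimeError(
                "rejection sampling failed 10^4 times; lower membrane_density "
                "or min_separation"
            )
        seed_state = int(rng.choice(len(labels), p=base_p))
        population = pop_labels[int(rng.choice(len(pop_labels), p=pop_w))]
        length = _draw_chain_length(rng, cont_p[seed_state])
        length = min(length, n_target - placed) or 1
        pos, normal = _sample_sphere_point(rng, center, r)
        if not builder.clear_of(pos):
            failures += 1
            continue
        rot = _normal_frame(normal, rng.uniform(0.0, 2 * np.pi))
        weights = w_mono if length == 1 else w_chain
        state = labels[int(rng.choice(len(labels), p=weights))]
        idx_prev = builder.add(pos, rot, state, population)
        placed += 1
        chain = [idx_prev]
        for _ in range(length - 1):
            prev_pos = builder.positions[idx_prev]
            prev_rot = builder.rotations[idx_prev]
            new_pos = prev_pos + prev_rot.T @ t_off
            radial = new_pos - center
            new_pos = center + r * radial / np.linalg.norm(radial)
            if not builder.clear_of(new_pos):
                break  # truncate chain at the obstruction
            new_normal = (new_pos - center) / r
            frame0 = _normal_frame(new_normal, 0.0)
            v = frame0 @ (prev_pos - new_pos)
            azim = np.arctan2(v[1], v[0]) - phi_lead
            new_rot = _rot_z_mat(-azim) @ frame0
            state = labels[int(rng.choice(len(labels), p=w_chain))]
            idx_new = builder.add(new_pos, new_rot, state, population)
            placed += 1
            truth.true_edges.add(
                (builder.tomogram_id, idx_new, idx_prev)
            )
            chain.append(idx_new)
            idx_prev = idx_new
            if placed >= n_target:
                break


def _fill_soluble(builder, rng, config, center, n_target, base_p, cont_p,
                  w_chain, w_mono, labels, t_off, l_off, truth):
    r_in = config.vesicle_radius - 150.0
    placed = 0
    failures = 0
    while placed < n_target:
        if failures > 10_000:
            raise RuntimeError("rejection sampling failed for soluble particles")
        seed_state = int(rng.choice(len(labels), p=base_p))
        length = _draw_chain_length(rng, cont_p[seed_state])
        length = min(length, n_target - placed) or 1
        pos = center + (r_in * rng.random() ** (1 / 3)) * _unit(rng)
        if not builder.clear_of(pos):
            failures += 1
            continue
        rot = _random_rotation(rng)
        weights = w_mono if length == 1 else w_chain
        state = labels[int(rng.choice(len(labels), p=weights))]
        idx_prev = builder.add(pos, rot, state, "soluble-EBP1")
        placed += 1
        for _ in range(length - 1):
            prev_pos = builder.positions[idx_prev]
            prev_rot = builder.rotations[idx_prev]
            new_pos = prev_pos + prev_rot.T @ t_off
            if not builder.clear_of(new_pos):
                break
            # any frame placing the previous particle at the leading offset:
            # align l_off with the back-vector, then randomize spin about it
            d = prev_pos - new_pos
            new_rot = _align_frame(l_off, d, rng)
            state = labels[int(rng.choice(len(labels), p=w_chain))]
            idx_new = builder.add(new_pos, new_rot, state, "soluble-EBP1")
            placed += 1
            truth.true_edges.add((builder.tomogram_id, idx_new, idx_prev))
            idx_prev = idx_new
            if placed >= n_target:
                break


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _align_frame(target: np.ndarray, source: np.ndarray, rng) -> np.ndarray:
    """Rotation R with R @ source parallel to target, random spin about target."""
    a = source / np.linalg.norm(source)
    b = target / np.linalg.norm(target)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        base = np.eye(3) if c > 0 else _rotation_about(_any_perp(a), np.pi)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        base = np.eye(3) + vx + vx @ vx / (1.0 + c)
    spin = _rotation_about(b, rng.uniform(0.0, 2 * np.pi))
    return spin @ base


def _any_perp(v: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, helper)
    return p / np.linalg.norm(p)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    k = axis / np.linalg.norm(axis)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * kx + (1 - np.cos(angle)) * (kx @ kx)


def _finalize(builder: _TomogramBuilder, rng, config: SceneConfig,
              truth: SceneTruth) -> pd.DataFrame:
    """Record ground truth, apply jitter, convert to table rows."""
    tid = builder.tomogram_id
    n = len(builder.positions)
    members = {
        pid
        for (t, a, b) in truth.true_edges
        if t == tid
        for pid in (a, b)
    }
    rows = []
    for i in range(n):
        truth.true_membership[(tid, i)] = i in members
        truth.frame_normals[(tid, i)] = builder.rotations[i][2].copy()
        pos = builder.positions[i] + rng.normal(
            0.0, config.positional_jitter_sd, size=3
        )
        rot = _small_rotation(rng, config.angular_jitter_sd) @ builder.rotations[i]
        rot_deg, tilt_deg, psi_deg = rotation_to_euler(rot)
        rows.append(
            (tid, i, pos[0], pos[1], pos[2], rot_deg, tilt_deg, psi_deg,
             builder.states[i], builder.populations[i])
        )
    return pd.DataFrame(
        rows,
        columns=["tomogram_id", "particle_id", "x", "y", "z",
                 "rot", "tilt", "psi", "state_label", "population_label"],
    )


def generate_association_dataset(
    state_outcome_probs: dict[str, dict[str, float]],
    n_tomograms: int,
    n_per_tomogram: int,
    tomogram_effect_sd: float = 0.5,
    seed: int = 0,
    state_weights: dict[str, float] | None = None,
    reference: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw observations from the association model itself (no geometry).

    ``state_outcome_probs[state][outcome]`` are the outcome probabilities at
    a typical tomogram (random effect u = 0).  Tomogram effects are drawn
    once per tomogram and non-reference category, added on the log-odds
    scale, and outcomes sampled from the resulting softmax -- exactly the
    data-generating process the mixed model assumes.

    Returns the observation table and the true parameters (log-odds and
    random-effect sd).
    """
    states = sorted(state_outcome_probs)
    outcomes = sorted(next(iter(state_outcome_probs.values())))
    for s, probs in state_outcome_probs.items():
        if sorted(probs) != outcomes:
            raise ValueError("all states must share the outcome set")
        if abs(sum(probs.values()) - 1.0) > 1e-8:
            raise ValueError(f"probabilities for state {s!r} do not sum to 1")
    if reference is None:
        reference = "none" if "none" in outcomes else outcomes[-1]
    nonref = [k for k in outcomes if k != reference]
    beta = {
        s: np.array(
            [np.log(state_outcome_probs[s][k] / state_outcome_probs[s][reference])
             for k in nonref]
        )
        for s in states
    }
    weights = np.array(
        [state_weights.get(s, 1.0) if state_weights else 1.0 for s in states],
        dtype=float,
    )
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    beta_mat = np.stack([beta[s] for s in states])  # (S, K-1)
    out_order = nonref + [reference]
    tids, out_states, out_outcomes = [], [], []
    for t in range(n_tomograms):
        u = rng.normal(0.0, tomogram_effect_sd, size=len(nonref))
        tid = f"tomo_{t:04d}"
        s_draw = rng.choice(len(states), size=n_per_tomogram, p=weights)
        eta = np.concatenate(
            [beta_mat[s_draw] + u, np.zeros((n_per_tomogram, 1))], axis=1
        )
        p = np.exp(eta - special.logsumexp(eta, axis=1, keepdims=True))
        k_draw = (rng.random(n_per_tomogram)[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        tids += [tid] * n_per_tomogram
        out_states += [states[s] for s in s_draw]
        out_outcomes += [out_order[k] for k in k_draw]
    df = pd.DataFrame(
        {"tomogram_id": tids, "state": out_states, "outcome": out_outcomes}
    )
    return df, {"beta": beta, "sd": tomogram_effect_sd, "reference": reference}
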