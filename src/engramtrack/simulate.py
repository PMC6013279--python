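"""Synthetic cohort generator for longitudinal IEG-imaging experiments.

Emulates the data structure of an 8-animal, 13-session two-photon c-Fos
imaging study on a radial-arm maze (RAM): per-cell fluorescence traces at
8 raw timepoints per session, ground-truth ensemble membership, and
per-session maze behaviour.

Generative model (per animal)
-----------------------------
Cells fall into disjoint functional groups drawn uniformly at random:

* **task ensemble** — the maze engram.  Its activation probability grows
  linearly over training (``emergence_base + emergence_rate * j`` for the
  j-th training session, capped at 1), reinstates on retention tests with
  the animal-specific ``reinstatement_fidelity``, and is silent elsewhere.
* **exploration ensemble** — engaged by first exposures to the maze
  (habituation and early training), with a linearly decaying probability;
  it is what habituation and the first training days share.
* **cage ensemble** — a small context ensemble for the dark home-cage
  negative-control sessions (C1, C2), giving the two controls their mutual,
  task-independent similarity.
* **nonspecific cells** — a small chronically active subpopulation (active
  with fixed probability on *every* session).  It supplies the uniform
  non-specific similarity floor that the control-based normalisation of the
  retention indices is designed to remove.
* **novelty set** — an independent set, ``novelty_multiplier`` times the
  task-ensemble size, engaged only by the novel-environment session.

Every cell additionally activates spuriously with ``baseline_rate`` per
session.  An activated (cell, session) adds ``active_amplitude`` to its
ΔF (T3 − T1); all cells receive symmetric double-exponential (Laplace)
ΔF noise with scale ``noise_scale``, reproducing the near-symmetric
double-exponential ΔF histogram with a long positive tail that the
threshold rule assumes.  Traces are built so that the meta-timepoint means
are exact: the two raw frames of each pair sit symmetrically around their
meta value.

Maze behaviour: five trials per RAM session; each visit is an error
(uniform random arm) with probability ``error_floor + error_scale *
(1 - s)`` where the session's ensemble stability ``s`` is the current
task-ensemble activation probability (training) or the animal's
reinstatement fidelity (retention tests), coupling forgetting to engram
reinstatement.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "DEFAULT_SESSION_SCHEDULE",
    "CohortConfig",
    "AnimalTruth",
    "SyntheticCohort",
    "ImageGeometry",
    "generate_cohort",
    "generate_behavior",
    "generate_image_stack",
    "default_grouping",
]


@dataclass(frozen=True)
class Session:
    """One imaged session: label, study day and experimental condition."""

    label: str
    day: int
    condition: str


#: The 13 imaged sessions: maze habituation, 7 of the 19 RAM training days,
#: two dark negative controls, two retention tests and one novelty session.
DEFAULT_SESSION_SCHEDULE = (
    Session("H", 0, "habituation"),
    Session("1", 1, "training"),
    Session("4", 4, "training"),
    Session("7", 7, "training"),
    Session("10", 10, "training"),
    Session("13", 13, "training"),
    Session("16", 16, "training"),
    Session("19", 19, "training"),
    Session("C1", 22, "control"),
    Session("R1", 25, "retention"),
    Session("N", 28, "novelty"),
    Session("C2", 40, "control"),
    Session("R2", 43, "retention"),
)

_CONDITIONS = {"habituation", "training", "control", "novelty", "retention"}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per session; intensity parameters are on the 8-bit
    fluorescence scale.  ``reinstatement_fidelity`` may be a scalar or one
    value per animal; the default spreads fidelities evenly over
    [0.3, 1.0] so the cohort spans strong to weak engram reinstatement.
    """

    n_animals: int = 8
    n_cells_per_animal: int = 800
    session_schedule: tuple = DEFAULT_SESSION_SCHEDULE
    # ensemble structure
    ensemble_fraction: float = 0.025
    emergence_base: float = 0.0
    emergence_rate: float = 0.15
    exploration_fraction: float = 0.025
    exploration_start: float = 0.8
    exploration_decay: float = 0.18
    cage_fraction: float = 0.02
    cage_rate: float = 0.65
    nonspecific_fraction: float = 0.015
    nonspecific_rate: float = 0.7
    novelty_multiplier: float = 1.3
    novelty_rate: float = 0.85
    reinstatement_fidelity: object = None  # scalar or per-animal sequence
    baseline_rate: float = 0.0025
    # fluorescence
    noise_scale: float = 5.0
    active_amplitude: float = 50.0
    baseline_level: float = 70.0
    baseline_spread: float = 6.0
    pair_jitter: float = 1.5
    t2_fraction: float = 0.6
    t4_fraction: float = 0.7
    # behaviour
    trials_per_session: int = 5
    max_visits: int = 8
    baited_arms: tuple = (2, 3, 4, 8)
    error_floor: float = 0.02
    error_scale: float = 0.9
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if int(self.n_animals) < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals}")
        if int(self.n_cells_per_animal) < 1:
            raise ValueError(
                f"n_cells_per_animal must be >= 1, got {self.n_cells_per_animal}"
            )
        labels = [s.label for s in self.session_schedule]
        if len(set(labels)) != len(labels):
            raise ValueError("session_schedule labels must be unique")
        for s in self.session_schedule:
            if s.condition not in _CONDITIONS:
                raise ValueError(
                    f"session_schedule: unknown condition {s.condition!r} "
                    f"(must be one of {sorted(_CONDITIONS)})"
                )
        for name in (
            "ensemble_fraction",
            "exploration_fraction",
            "cage_fraction",
            "nonspecific_fraction",
            "baseline_rate",
            "cage_rate",
            "nonspecific_rate",
            "novelty_rate",
            "error_floor",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in (
            "emergence_base",
            "emergence_rate",
            "exploration_start",
            "exploration_decay",
            "novelty_multiplier",
            "error_scale",
            "t2_fraction",
            "t4_fraction",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in (
            "noise_scale",
            "active_amplitude",
            "baseline_level",
            "baseline_spread",
            "pair_jitter",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        fid = self.fidelities()
        if not np.isfinite(fid).all() or ((fid < 0) | (fid > 1)).any():
            raise ValueError(
                f"reinstatement_fidelity values must lie in [0, 1], got {fid!r}"
            )
        arms = set(self.baited_arms)
        if not arms or not arms <= set(range(1, 9)):
            raise ValueError(f"baited_arms must be a subset of 1..8, got {self.baited_arms}")

    # -- derived quantities ---------------------------------------------
    def fidelities(self) -> np.ndarray:
        """Per-animal reinstatement fidelity, resolving the default spread."""
        fid = self.reinstatement_fidelity
        if fid is None:
            if self.n_animals == 1:
                return np.array([0.65])
            return np.linspace(0.3, 1.0, self.n_animals)
        arr = np.atleast_1d(np.asarray(fid, dtype=float))
        if arr.size == 1:
            return np.full(self.n_animals, arr[0])
        if arr.size != self.n_animals:
            raise ValueError(
                "reinstatement_fidelity must be a scalar or one value per animal"
            )
        return arr

    @property
    def session_labels(self) -> list[str]:
        return [s.label for s in self.session_schedule]

    def training_sessions(self) -> list[Session]:
        return [s for s in self.session_schedule if s.condition == "training"]

    def ram_sessions(self) -> list[Session]:
        """Sessions run on the maze and scored for errors (training + retention)."""
        return [
            s for s in self.session_schedule if s.condition in ("training", "retention")
        ]

    def task_probability(self, session: Session) -> float:
        """Task-ensemble activation probability for a training session."""
        order = [s.label for s in self.training_sessions()]
        j = order.index(session.label) + 1
        return min(1.0, self.emergence_base + self.emergence_rate * j)

    def exploration_probability(self, session: Session) -> float:
        """Exploration-ensemble activation probability (H and early training)."""
        if session.condition == "habituation":
            j = 0
        elif session.condition == "training":
            j = [s.label for s in self.training_sessions()].index(session.label) + 1
        else:
            return 0.0
        return max(0.0, self.exploration_start - self.exploration_decay * j)

    def retention_probability(self, session: Session, fidelity: float) -> float:
        """Ensemble reactivation probability on a retention test.

        ``reinstatement_fidelity`` is the reactivation probability at the
        *final* retention test; earlier tests interpolate linearly in
        elapsed time since the last training day, so forgetting accrues
        with delay (the first test, 6 days out, sits a quarter of the way
        from perfect reinstatement to the final-fidelity level).
        """
        ret_days = [s.day for s in self.session_schedule if s.condition == "retention"]
        training = self.training_sessions()
        last_train = max(s.day for s in training) if training else min(ret_days) - 1
        final = max(ret_days)
        if final <= last_train:
            return float(fidelity)
        frac = (session.day - last_train) / (final - last_train)
        return float(1.0 - (1.0 - fidelity) * frac)

    def stability(self, session: Session, fidelity: float) -> float:
        """Ensemble stability driving maze performance on a RAM session."""
        if session.condition == "training":
            return self.task_probability(session)
        if session.condition == "retention":
            return self.retention_probability(session, fidelity)
        raise ValueError(f"session {session.label!r} is not a RAM session")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session_schedule"] = [
            {"label": s.label, "day": s.day, "condition": s.condition}
            for s in self.session_schedule
        ]
        d["reinstatement_fidelity"] = self.fidelities().tolist()
        d["baited_arms"] = list(self.baited_arms)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        sched = d.get("session_schedule")
        if sched is not None and sched and not isinstance(sched[0], Session):
            d["session_schedule"] = tuple(
                Session(str(s["label"]), int(s["day"]), str(s["condition"]))
                for s in sched
            )
        if "baited_arms" in d:
            d["baited_arms"] = tuple(d["baited_arms"])
        return cls(**d)


@dataclass(frozen=True)
class AnimalTruth:
    """Ground truth for one animal: group membership and true activations."""

    ensemble: np.ndarray          # task-ensemble cell indices
    exploration: np.ndarray
    cage: np.ndarray
    nonspecific: np.ndarray
    novelty_set: np.ndarray
    activation: np.ndarray        # bool, (n_cells, n_sessions): truly activated
    fidelity: float


@dataclass
class SyntheticCohort:
    """Generated cohort: traces, ground truth, behaviour and config echo.

    ``traces`` is (n_animals, n_cells, n_sessions, 8) on the 8-bit scale;
    ``behavior[i][label]`` is the list of arm-visit trials for animal ``i``
    on RAM session ``label``.
    """

    traces: np.ndarray
    truth: list
    behavior: list
    config: CohortConfig

    @property
    def session_labels(self) -> list[str]:
        return self.config.session_labels

    def traces_frame(self) -> pd.DataFrame:
        """Long-format trace table (animal, cell, session, timepoint, value)."""
        a, c, s, t = self.traces.shape
        idx = pd.MultiIndex.from_product(
            [range(a), range(c), self.session_labels, range(1, t + 1)],
            names=["animal", "cell", "session", "timepoint"],
        )
        return pd.DataFrame(
            {"value": self.traces.reshape(-1)}, index=idx
        ).reset_index()

    def behavior_frame(self) -> pd.DataFrame:
        """Long-format visit log (animal, session, trial, visit_order, arm)."""
        rows = []
        for animal, sessions in enumerate(self.behavior):
            for label, trials in sessions.items():
                for trial, visits in enumerate(trials):
                    for order, arm in enumerate(visits):
                        rows.append((animal, label, trial, order, arm))
        return pd.DataFrame(
            rows, columns=["animal", "session", "trial", "visit_order", "arm"]
        )

    def truth_dict(self) -> dict:
        return {
            str(i): {
                "ensemble": t.ensemble.tolist(),
                "exploration": t.exploration.tolist(),
                "cage": t.cage.tolist(),
                "nonspecific": t.nonspecific.tolist(),
                "novelty_set": t.novelty_set.tolist(),
                "activation": t.activation.astype(int).tolist(),
                "fidelity": float(t.fidelity),
            }
            for i, t in enumerate(self.truth)
        }


def _animal_rng(seed: int, animal: int) -> np.random.Generator:
    # fixed per-animal stream so cohorts are reproducible under parallel gen
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(animal,)))


def _assign_groups(rng: np.random.Generator, cfg: CohortConfig) -> dict[str, np.ndarray]:
    n = cfg.n_cells_per_animal
    sizes = {
        "ensemble": round(cfg.ensemble_fraction * n),
        "exploration": round(cfg.exploration_fraction * n),
        "cage": round(cfg.cage_fraction * n),
        "nonspecific": round(cfg.nonspecific_fraction * n),
    }
    sizes["novelty_set"] = round(cfg.novelty_multiplier * sizes["ensemble"])
    if sum(sizes.values()) > n:
        raise ValueError("ensemble fractions sum to more than the cell count")
    perm = rng.permutation(n)
    groups, start = {}, 0
    for name, size in sizes.items():
        groups[name] = np.sort(perm[start : start + size])
        start += size
    return groups


def _activation_matrix(
    rng: np.random.Generator,
    cfg: CohortConfig,
    groups: Mapping[str, np.ndarray],
    fidelity: float,
) -> np.ndarray:
    n, sessions = cfg.n_cells_per_animal, cfg.session_schedule
    act = rng.random((n, len(sessions))) < cfg.baseline_rate
    for k, sess in enumerate(sessions):
        draws = rng.random(n)
        p = np.zeros(n)
        if sess.condition == "training":
            p[groups["ensemble"]] = cfg.task_probability(sess)
            p[groups["exploration"]] = cfg.exploration_probability(sess)
        elif sess.condition == "habituation":
            p[groups["exploration"]] = cfg.exploration_probability(sess)
            p[groups["ensemble"]] = cfg.emergence_base
        elif sess.condition == "retention":
            p[groups["ensemble"]] = cfg.retention_probability(sess, fidelity)
        elif sess.condition == "control":
            p[groups["cage"]] = cfg.cage_rate
        elif sess.condition == "novelty":
            p[groups["novelty_set"]] = cfg.novelty_rate
        p[groups["nonspecific"]] = np.maximum(
            p[groups["nonspecific"]], cfg.nonspecific_rate
        )
        act[:, k] |= draws < p
    return act


def _render_traces(
    rng: np.random.Generator, cfg: CohortConfig, activation: np.ndarray
) -> np.ndarray:
    """Raw (cell, session, 8) traces realising ΔF = amplitude·act + Laplace."""
    n, s = activation.shape
    base_cell = np.clip(
        rng.normal(cfg.baseline_level, cfg.baseline_spread, size=n), 10.0, 200.0
    )
    t1 = base_cell[:, None] + rng.laplace(0.0, max(cfg.noise_scale, 1e-12), (n, s)) * (
        1.0 if cfg.noise_scale > 0 else 0.0
    )
    dnoise = (
        rng.laplace(0.0, cfg.noise_scale, (n, s)) if cfg.noise_scale > 0 else np.zeros((n, s))
    )
    df = activation * cfg.active_amplitude + dnoise
    t3 = t1 + df
    t2 = t1 + cfg.t2_fraction * df
    t4 = t1 + cfg.t4_fraction * df
    meta = np.stack([t1, t2, t3, t4], axis=-1)
    meta = np.clip(meta, 2.0, 253.0)
    jitter = np.clip(rng.normal(0.0, cfg.pair_jitter, meta.shape), -2.0, 2.0) if (
        cfg.pair_jitter > 0
    ) else np.zeros(meta.shape)
    raw = np.empty((n, s, 8))
    raw[..., 0::2] = meta + jitter
    raw[..., 1::2] = meta - jitter
    return raw


def _simulate_trial(
    rng: np.random.Generator, cfg: CohortConfig, error_prob: float
) -> list[int]:
    baited = list(cfg.baited_arms)
    visits: list[int] = []
    rewarded: set[int] = set()
    while len(visits) < cfg.max_visits and len(rewarded) < len(baited):
        if rng.random() < error_prob:
            # erroneous visits head for never-baited arms (reference errors)
            non_baited = sorted(set(range(1, 9)) - set(baited)) or baited
            arm = int(non_baited[int(rng.integers(len(non_baited)))])
        else:
            remaining = [a for a in baited if a not in rewarded]
            arm = remaining[int(rng.integers(len(remaining)))]
        visits.append(arm)
        if arm in baited:
            rewarded.add(arm)
    return visits


def generate_behavior(
    truth: AnimalTruth,
    config: CohortConfig,
    rng: np.random.Generator | int | None = None,
) -> dict[str, list]:
    """Simulate arm-visit trials for every RAM session of one animal.

    The per-visit error probability is ``error_floor + error_scale *
    (1 - stability)``, with stability the session's task-ensemble
    activation probability (training) or the animal's reinstatement
    fidelity (retention), so reference errors fall as the engram
    stabilises and rise at retention in proportion to 1 − fidelity.
    """
    ram = config.ram_sessions()
    if not ram:
        raise ValueError("session schedule contains no RAM sessions")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out: dict[str, list] = {}
    for sess in ram:
        s = config.stability(sess, truth.fidelity)
        eps = float(np.clip(config.error_floor + config.error_scale * (1.0 - s), 0.0, 1.0))
        out[sess.label] = [
            _simulate_trial(rng, config, eps) for _ in range(config.trials_per_session)
        ]
    return out


def generate_cohort(config: CohortConfig | None = None, **kwargs) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortConfig`.

    Identical ``(config, seed)`` reproduce bit-identical output; each
    animal draws from its own seed stream.
    """
    if config is None:
        config = CohortConfig(**kwargs)
    elif kwargs:
        config = dataclasses.replace(config, **kwargs)
    config.validate()
    fid = config.fidelities()
    n_sessions = len(config.session_schedule)
    traces = np.empty(
        (config.n_animals, config.n_cells_per_animal, n_sessions, 8)
    )
    truth: list[AnimalTruth] = []
    behavior: list[dict] = []
    for i in range(config.n_animals):
        rng = _animal_rng(config.seed, i)
        groups = _assign_groups(rng, config)
        activation = _activation_matrix(rng, config, groups, fid[i])
        traces[i] = _render_traces(rng, config, activation)
        record = AnimalTruth(
            ensemble=groups["ensemble"],
            exploration=groups["exploration"],
            cage=groups["cage"],
            nonspecific=groups["nonspecific"],
            novelty_set=groups["novelty_set"],
            activation=activation,
            fidelity=float(fid[i]),
        )
        truth.append(record)
        behavior.append(generate_behavior(record, config, rng))
    return SyntheticCohort(traces=traces, truth=truth, behavior=behavior, config=config)


def default_grouping(config: CohortConfig) -> dict[str, list[str]]:
    """Partition of the schedule into condition blocks for collapsing."""
    blocks: dict[str, list[str]] = {}
    for s in config.session_schedule:
        blocks.setdefault(s.condition, []).append(s.label)
    return blocks


# ---------------------------------------------------------------------------
# synthetic image stacks


@dataclass(frozen=True)
class ImageGeometry:
    """Geometry of a synthetic imaging volume (desk-scale defaults)."""

    nx: int = 256
    ny: int = 256
    nz: int = 60
    um_per_px: float = 400.0 / 1024.0
    um_per_plane: float = 2.0
    soma_radius_um: float = 7.0
    blob_sigma_um: float = 3.0
    blob_sigma_planes: float = 1.5
    background: float = 20.0
    background_noise: float = 2.0

    @property
    def mask_radius_px(self) -> float:
        return self.soma_radius_um / self.um_per_px


def generate_image_stack(
    cells: Sequence[Mapping],
    geometry: ImageGeometry | None = None,
    seed: int | None = 0,
) -> tuple[np.ndarray, list[dict]]:
    """Render cells as 3-D Gaussian blobs over timepoints.

    ``cells`` is a sequence of mappings with keys ``cell_id``, ``x``, ``y``,
    ``z`` (pixel/plane coordinates) and ``values`` (peak brightness per
    timepoint).  Returns ``(stack, masks)`` where ``stack`` has shape
    (n_timepoints, nz, ny, nx) and each mask records the circular 7-µm ROI
    at the cell's brightest z-plane.  Warns when more than 5% of
    above-background pixels are claimed by several cells.
    """
    geom = geometry or ImageGeometry()
    rng = np.random.default_rng(seed)
    n_t = max((len(c["values"]) for c in cells), default=1)
    for c in cells:
        if len(c["values"]) != n_t:
            raise ValueError("all cells must provide the same number of timepoints")
    stack = np.full((n_t, geom.nz, geom.ny, geom.nx), float(geom.background))
    if geom.background_noise > 0:
        stack += rng.normal(0.0, geom.background_noise, stack.shape)
    sx = geom.blob_sigma_um / geom.um_per_px
    sz = geom.blob_sigma_planes
    zz = np.arange(geom.nz, dtype=float)
    yy = np.arange(geom.ny, dtype=float)
    xx = np.arange(geom.nx, dtype=float)
    claimed = np.zeros((geom.nz, geom.ny, geom.nx), dtype=np.int16)
    masks: list[dict] = []
    for c in cells:
        cx, cy, cz = float(c["x"]), float(c["y"]), float(c["z"])
        if not (0 <= cx < geom.nx and 0 <= cy < geom.ny and 0 <= cz < geom.nz):
            raise ValueError(f"cell {c.get('cell_id')} centre outside the volume")
        gz = np.exp(-0.5 * ((zz - cz) / sz) ** 2)
        gy = np.exp(-0.5 * ((yy - cy) / sx) ** 2)
        gx = np.exp(-0.5 * ((xx - cx) / sx) ** 2)
        blob = gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        claimed += blob > 0.05
        for k, v in enumerate(c["values"]):
            stack[k] += float(v) * blob
        masks.append(
            {
                "cell_id": c.get("cell_id", len(masks)),
                "center_x": cx,
                "center_y": cy,
                "z": int(np.argmax(gz)),
                "radius_px": geom.mask_radius_px,
            }
        )
    multi = claimed > 1
    footprint = claimed > 0
    if footprint.any() and multi.sum() / footprint.sum() > 0.05:
        warnings.warn(
            f"{100 * multi.sum() / footprint.sum():.1f}% of cell-footprint pixels "
            "are claimed by more than one cell",
            stacklevel=2,
        )
    return np.clip(stack, 0.0, None), masks
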