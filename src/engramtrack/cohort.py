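"""Cohort-level synthesis: behaviour scoring, clustering and correlations.

Ties the stages together: ΔF extraction from traces, per-animal active-cell
calling, the 13×13 pairwise similarity matrices with exact p-values,
Fisher/Bonferroni meta-analysis across animals, average-linkage clustering
of the mean similarity matrix, radial-arm-maze error scoring, and the
engram-stability-versus-forgetting correlations.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import activity as _activity
from . import fluorescence as _fluo
from . import overlap as _overlap
from .simulate import CohortConfig, SyntheticCohort, default_grouping, generate_cohort

__all__ = [
    "BehaviorSession",
    "Dendrogram",
    "score_session",
    "error_difference",
    "correlate",
    "pearson_pvalue",
    "cluster_conditions",
    "compute_deltas",
    "detect_activity",
    "similarity_matrices",
    "combine_across_animals",
    "analyze_cohort",
    "CohortReport",
    "run_pipeline",
]

ALL_ARMS = frozenset(range(1, 9))


@dataclass(frozen=True)
class BehaviorSession:
    """Scored maze session: reference- and working-memory error counts.

    A reference-memory (RM) error is any visit to a never-baited arm (the
    complement of the baited set); a working-memory (WM) error is any
    re-entry into an arm already visited within the same trial.
    """

    animal_id: str
    label: str
    trials: tuple
    baited: frozenset
    rm_errors: int
    wm_errors: int


def score_session(
    trials: Sequence[Sequence[int]],
    baited_set: Sequence[int] = (2, 3, 4, 8),
    animal_id: str = "",
    label: str = "",
) -> BehaviorSession:
    """Count RM and WM errors over a session's trials."""
    baited = frozenset(int(a) for a in baited_set)
    if not baited <= ALL_ARMS:
        raise ValueError(f"baited arms must be within 1..8, got {sorted(baited)}")
    rm = wm = 0
    clean: list[tuple] = []
    for visits in trials:
        seen: set[int] = set()
        for arm in visits:
            arm = int(arm)
            if arm not in ALL_ARMS:
                raise ValueError(f"arm id {arm} outside 1..8")
            if arm not in baited:
                rm += 1
            if arm in seen:
                wm += 1
            seen.add(arm)
        clean.append(tuple(int(a) for a in visits))
    return BehaviorSession(
        animal_id=animal_id,
        label=label,
        trials=tuple(clean),
        baited=baited,
        rm_errors=rm,
        wm_errors=wm,
    )


def error_difference(
    errors: Mapping[str, float],
    order: Sequence[str] | None = None,
    ref: str = "19",
) -> dict[str, float]:
    """Signed error difference between each session and the reference.

    The difference is taken in chronological order (later session minus
    earlier session): sessions before the reference yield
    ``errors(ref) − errors(s)`` — negative while performance is still
    improving — and sessions after it yield ``errors(s) − errors(ref)``,
    positive when the memory has degraded.  ``diff(ref) = 0``.
    """
    if ref not in errors:
        raise ValueError(f"reference session {ref!r} not among the scored sessions")
    order = list(order) if order is not None else list(errors)
    if set(order) != set(errors):
        raise ValueError("order must list exactly the scored sessions")
    ref_pos = order.index(ref)
    out: dict[str, float] = {}
    for pos, s in enumerate(order):
        if pos <= ref_pos:
            out[s] = float(errors[ref]) - float(errors[s])
        else:
            out[s] = float(errors[s]) - float(errors[ref])
    return out


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via t = r sqrt(n−2) / sqrt(1−r²), n−2 df."""
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, pearson_pvalue(r, x.size)


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage merge tree over the experimental conditions."""

    linkage: np.ndarray
    labels: tuple

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> dict[str, int]:
        """Partition the leaves into ``k`` flat clusters."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))

    def to_newick(self) -> str:
        from skbio.tree import TreeNode  # heavy import kept lazy

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        return str(tree)


def cluster_conditions(
    similarity: pd.DataFrame, metric: str = "similarity"
) -> Dendrogram:
    """Cluster conditions by between-group (average/UPGMA) linkage.

    ``metric="similarity"`` (default) clusters on the dissimilarity
    D = 1 − J, using the study's own statistic as the metric;
    ``metric="rows"`` clusters on Euclidean distance between matrix rows.
    """
    mat = similarity.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("similarity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("similarity matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-8):
        raise ValueError("similarity matrix must have a unit diagonal")
    labels = tuple(str(c) for c in similarity.columns)
    if metric == "similarity":
        dist = 1.0 - mat
        np.fill_diagonal(dist, 0.0)
        z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    elif metric == "rows":
        z = hierarchy.linkage(mat, method="average", metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return Dendrogram(linkage=z, labels=labels)


# ---------------------------------------------------------------------------
# cohort pipeline


def compute_deltas(cohort: SyntheticCohort) -> np.ndarray:
    """ΔF = T3 − T1 for every (animal, cell, session) from raw traces."""
    reduced = _fluo.reduce_timepoints(cohort.traces)
    return reduced[..., 2] - reduced[..., 0]


def detect_activity(cohort: SyntheticCohort) -> list[_activity.ActivityMatrix]:
    """Per-animal pooled-threshold active-cell calling."""
    deltas = compute_deltas(cohort)
    labels = cohort.session_labels
    out = []
    for i in range(deltas.shape[0]):
        frame = pd.DataFrame(deltas[i], columns=labels)
        thr = _activity.pooled_threshold(deltas[i])
        out.append(_activity.call_active(frame, thr, animal_id=str(i)))
    return out


def similarity_matrices(
    matrices: Sequence[_activity.ActivityMatrix],
) -> tuple[list[pd.DataFrame], list[pd.DataFrame], pd.DataFrame]:
    """Per-animal Jaccard and p-value matrices plus the cohort-mean matrix.

    For each animal the null universe is its own active-cell pool.  A
    session with no active cells yields J = 0 / p = 1 against every
    partner (with a warning from the overlap layer).
    """
    j_mats, p_mats = [], []
    for m in matrices:
        pool = _activity.active_cell_pool(m)
        labels = list(m.active.columns)
        sets = {
            s: frozenset(m.active.index[m.active[s]]) for s in labels
        }
        j = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
        p = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
        for s1, s2 in itertools.combinations(labels, 2):
            if pool.t == 0:
                test = _overlap.OverlapTest(0, 0, 0, 0, 0.0, 1.0)
            else:
                test = _overlap.overlap_test(sets[s1], sets[s2], pool.t)
            j.loc[s1, s2] = j.loc[s2, s1] = test.jaccard
            p.loc[s1, s2] = p.loc[s2, s1] = test.p_value
        j_mats.append(j)
        p_mats.append(p)
    mean_j = sum(j_mats) / len(j_mats)
    return j_mats, p_mats, mean_j


def combine_across_animals(
    matrices: Sequence[_activity.ActivityMatrix],
    p_mats: Sequence[pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-combine per-animal p-values for every session pair.

    Animals on which either session of a pair had zero active cells carry
    no overlap information and are excluded from that pair's combination
    (logged via warning).  Returns a table with one row per session pair:
    Fisher statistic, df, combined p and the Bonferroni-adjusted
    significance flag at ``alpha / n_pairs``.
    """
    labels = list(p_mats[0].columns)
    pairs = list(itertools.combinations(labels, 2))
    n_tests = len(pairs)
    adj = _overlap.bonferroni_alpha(alpha, n_tests)
    counts = [
        {s: int(m.active[s].sum()) for s in labels} for m in matrices
    ]
    rows = []
    for s1, s2 in pairs:
        ps = [
            float(pm.loc[s1, s2])
            for pm, cnt in zip(p_mats, counts)
            if cnt[s1] > 0 and cnt[s2] > 0
        ]
        excluded = len(p_mats) - len(ps)
        if excluded:
            warnings.warn(
                f"pair ({s1}, {s2}): excluding {excluded} animal(s) with an "
                "empty active set from Fisher combination",
                stacklevel=2,
            )
        if ps:
            res = _overlap.fisher_combine(ps)
            stat, df, p = res.statistic, res.df, res.p_value
        else:
            stat, df, p = 0.0, 0, 1.0
        rows.append(
            {
                "session_a": s1,
                "session_b": s2,
                "n_animals": len(ps),
                "statistic": stat,
                "df": df,
                "p_value": p,
                "significant": p < adj,
            }
        )
    return pd.DataFrame(rows)


def _mean_timecourse(cohort: SyntheticCohort) -> np.ndarray:
    """Per-animal mean fluorescence at T1..T4 across RAM sessions."""
    reduced = _fluo.reduce_timepoints(cohort.traces)
    labels = cohort.session_labels
    ram = [labels.index(s.label) for s in cohort.config.ram_sessions()]
    return reduced[:, :, ram, :].mean(axis=(1, 2))


@dataclass
class CohortReport:
    """Everything the end-to-end analysis computes for one cohort."""

    config: CohortConfig
    activity: list
    percent_active: pd.DataFrame          # animals × sessions
    similarity: list                      # per-animal J matrices
    p_values: list                        # per-animal p matrices
    mean_similarity: pd.DataFrame
    combined: pd.DataFrame
    dendrogram: Dendrogram
    behavior: pd.DataFrame                # animal, session, rm/wm errors
    error_differences: pd.DataFrame       # animals × RAM sessions (vs ref)
    normalized: object                    # NormalizedSimilarity
    reactivation: pd.DataFrame
    correlations: dict
    timecourse: np.ndarray                # standardized (animals × 4)

    def summary(self) -> dict:
        """JSON-serialisable summary of the headline numbers."""
        pa = self.percent_active.mean(axis=0)
        return {
            "n_animals": int(self.config.n_animals),
            "n_cells_per_animal": int(self.config.n_cells_per_animal),
            "percent_active_by_session": {k: float(v) for k, v in pa.items()},
            "pool_percent_by_animal": [
                100.0 * _activity.active_cell_pool(m).t / m.total_cells
                for m in self.activity
            ],
            "mean_similarity": {
                f"{a}|{b}": float(self.mean_similarity.loc[a, b])
                for a, b in itertools.combinations(self.mean_similarity.columns, 2)
            },
            "n_significant_pairs": int(self.combined["significant"].sum()),
            "n_pairs": int(len(self.combined)),
            "cluster_assignment_k4": self.dendrogram.cut(4),
            "correlations": {
                k: {"r": float(r), "p": float(p), "n": int(n)}
                for k, (r, p, n) in self.correlations.items()
            },
            "normalized_similarity": {
                "r2_19": [float(v) for v in self.normalized.r2_19],
                "r2_r1": [float(v) for v in self.normalized.r2_r1],
                "scale": float(self.normalized.scale),
            },
            "timecourse_standardized_mean": [
                float(v) for v in self.timecourse.mean(axis=0)
            ],
        }


def _behavior_table(cohort: SyntheticCohort) -> pd.DataFrame:
    rows = []
    for animal, sessions in enumerate(cohort.behavior):
        for label, trials in sessions.items():
            scored = score_session(
                trials,
                cohort.config.baited_arms,
                animal_id=str(animal),
                label=label,
            )
            rows.append(
                {
                    "animal": animal,
                    "session": label,
                    "rm_errors": scored.rm_errors,
                    "wm_errors": scored.wm_errors,
                }
            )
    return pd.DataFrame(rows)


def analyze_cohort(
    cohort: SyntheticCohort,
    alpha: float = 0.05,
    reference_session: str = "19",
) -> CohortReport:
    """Run the full analysis chain on a cohort.

    detect → similarity + exact p-values → Fisher/Bonferroni → clustering
    → behaviour scoring → error differences → normalised retention indices
    → stability-vs-forgetting correlations.
    """
    matrices = detect_activity(cohort)
    labels = cohort.session_labels
    percent = pd.DataFrame(
        [
            {s: _activity.percent_active(m, s) for s in labels}
            for m in matrices
        ]
    )
    j_mats, p_mats, mean_j = similarity_matrices(matrices)
    combined = combine_across_animals(matrices, p_mats, alpha=alpha)
    dendro = cluster_conditions(mean_j)

    behavior = _behavior_table(cohort)
    ram_order = [s.label for s in cohort.config.ram_sessions()]
    err = behavior.pivot(index="animal", columns="session", values="rm_errors")
    err = err[ram_order]
    diffs = pd.DataFrame(
        [
            error_difference(err.loc[a].to_dict(), order=ram_order, ref=reference_session)
            for a in err.index
        ],
        index=err.index,
    )

    j_r2_19 = np.array([m.loc["R2", "19"] for m in j_mats])
    j_r2_r1 = np.array([m.loc["R2", "R1"] for m in j_mats])
    j_r2_c1 = np.array([m.loc["R2", "C1"] for m in j_mats])
    try:
        normalized = _overlap.normalize_similarity(j_r2_r1, j_r2_19, j_r2_c1)
    except ValueError as exc:  # e.g. every animal has J(R2,C1) = 0
        warnings.warn(f"similarity normalisation degenerate: {exc}", stacklevel=2)
        normalized = _overlap.NormalizedSimilarity(
            r2_r1=np.array([]),
            r2_19=np.array([]),
            scale=float("nan"),
            included=np.zeros(len(j_mats), dtype=bool),
        )
    inc = normalized.included

    correlations = {}
    for key, yvals, xdiff in (
        ("r2_19", normalized.r2_19, (err["R2"] - err["19"]).to_numpy(dtype=float)[inc]),
        ("r2_r1", normalized.r2_r1, (err["R2"] - err["R1"]).to_numpy(dtype=float)[inc]),
    ):
        try:
            r, p = correlate(xdiff, np.asarray(yvals))
            correlations[key] = (r, p, len(yvals))
        except ValueError as exc:  # degenerate cohort (e.g. constant errors)
            warnings.warn(f"correlation {key} undefined: {exc}", stacklevel=2)
            correlations[key] = (float("nan"), float("nan"), len(yvals))

    react_rows = []
    for i, m in enumerate(matrices):
        pool = _activity.active_cell_pool(m)
        r2 = set(m.active.index[m.active["R2"]])
        for ref in ("19", "R1"):
            ref_set = set(m.active.index[m.active[ref]])
            if not ref_set or pool.t == 0:
                score = np.nan
                norm = np.nan
            else:
                score = _overlap.reactivation_score(ref_set, r2)
                norm = _overlap.chance_normalized_reactivation(
                    score, len(ref_set), len(r2), pool.t
                ) if r2 else 0.0
            react_rows.append(
                {"animal": i, "reference": ref, "score": score, "chance_normalized": norm}
            )

    timecourse = _fluo.standardize_timecourse(_mean_timecourse(cohort))

    return CohortReport(
        config=cohort.config,
        activity=matrices,
        percent_active=percent,
        similarity=j_mats,
        p_values=p_mats,
        mean_similarity=mean_j,
        combined=combined,
        dendrogram=dendro,
        behavior=behavior,
        error_differences=diffs,
        normalized=normalized,
        reactivation=pd.DataFrame(react_rows),
        correlations=correlations,
        timecourse=timecourse,
    )


def run_pipeline(
    config: CohortConfig | Mapping | str | None = None,
    outdir=None,
    seed: int | None = None,
    alpha: float = 0.05,
    make_figures: bool = True,
) -> dict:
    """End-to-end run: simulate → analyse → write the report bundle.

    ``config`` may be a :class:`CohortConfig`, a mapping, or a path to a
    YAML file.  When ``outdir`` is given the bundle is written there:
    trace/behaviour/activity CSVs, per-animal and mean similarity CSVs,
    combined-p CSV, Newick dendrogram, heatmap figure and ``report.json``
    (byte-identical across reruns at a fixed seed).  Returns the summary
    dictionary.
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read_text"):
        import yaml
        from pathlib import Path

        path = Path(config)
        if not path.exists():
            raise FileNotFoundError(
                f"config file {path} not found; expected a YAML CohortConfig "
                "(see CohortConfig.to_dict for the schema)"
            )
        config = CohortConfig.from_dict(yaml.safe_load(path.read_text()))
    elif isinstance(config, Mapping):
        config = CohortConfig.from_dict(config)
    elif config is None:
        config = CohortConfig()
    if seed is not None:
        import dataclasses

        config = dataclasses.replace(config, seed=int(seed))

    cohort = generate_cohort(config)
    report = analyze_cohort(cohort, alpha=alpha)
    summary = report.summary()
    summary["seed"] = int(config.seed)
    summary["thresholds"] = [float(m.threshold) for m in report.activity]

    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        import yaml

        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        cohort.traces_frame().to_csv(out / "traces.csv", index=False)
        cohort.behavior_frame().to_csv(out / "behavior.csv", index=False)
        (out / "truth.json").write_text(json.dumps(cohort.truth_dict(), sort_keys=True))
        deltas = compute_deltas(cohort)
        act_rows = []
        for i, m in enumerate(report.activity):
            for ci in m.active.index:
                for s in m.active.columns:
                    act_rows.append(
                        (i, ci, s, deltas[i, ci, list(m.active.columns).index(s)],
                         bool(m.active.loc[ci, s]))
                    )
        pd.DataFrame(
            act_rows, columns=["animal", "cell", "session", "delta_f", "active"]
        ).to_csv(out / "activity.csv", index=False)
        report.percent_active.to_csv(out / "percent_active.csv")
        for i, (j, p) in enumerate(zip(report.similarity, report.p_values)):
            j.to_csv(out / f"similarity_animal{i}.csv")
            p.to_csv(out / f"pvalues_animal{i}.csv")
        report.mean_similarity.to_csv(out / "similarity_mean.csv")
        # Fig-3D-style layout: J below the diagonal, log10 combined p above
        layout = report.mean_similarity.copy()
        for row in report.combined.itertuples():
            layout.loc[row.session_a, row.session_b] = np.log10(max(row.p_value, 1e-300))
        layout.to_csv(out / "similarity_with_log10p.csv")
        report.combined.to_csv(out / "combined_p.csv", index=False)
        (out / "dendrogram.nwk").write_text(report.dendrogram.to_newick())
        report.behavior.to_csv(out / "behavior_scores.csv", index=False)
        report.error_differences.to_csv(out / "error_differences.csv")
        report.reactivation.to_csv(out / "reactivation.csv", index=False)
        (out / "report.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1)
        )
        if make_figures:
            _write_heatmap(report.mean_similarity, out / "similarity_heatmap.png")
    return summary


def _write_heatmap(mean_j: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(mean_j.to_numpy(), cmap="magma", vmin=0.0)
    ax.set_xticks(range(len(mean_j.columns)), mean_j.columns)
    ax.set_yticks(range(len(mean_j.index)), mean_j.index)
    ax.set_title("Mean similarity index")
    fig.colorbar(im, ax=ax, label="J")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
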