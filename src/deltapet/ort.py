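"""Ordinal-trend covariance-pattern analysis for paired-condition scans.

A supervised-PCA variant for two-condition (pre/post) scan sets: the
scans are normalized, flattened over the brain mask and voxel-wise
centered; principal components are extracted by SVD; candidate component
subsets (singletons and pairs) are combined by least squares against the
condition indicator and scored by AIC; the winning unit-norm voxel
pattern is oriented so that subject expression increases from the first
to the second condition for the majority of subjects.

Inference: a permutation test that flips each subject's condition labels
independently with probability 1/2 and refits the full model, and a
subject-level bootstrap for voxel-weight reliability (one-tailed
sign-crossing p per voxel).  Both p-value conventions use add-one
numerators and denominators, so p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from deltapet.errors import FitError, InputError
from deltapet.roi import VolumeImage, normalize_to_brain_mean

__all__ = [
    "ScanMatrix",
    "OrtModel",
    "NodalExpression",
    "OrtInference",
    "build_scan_matrix",
    "fit_ort",
    "ordinal_statistic",
    "permutation_test",
    "bootstrap_voxel_pmap",
    "nodal_expression_delta",
]


@dataclass
class ScanMatrix:
    """Centered scan-by-voxel data with its centering record.

    Rows are subject-major with condition order (first, second) per
    subject; columns are in-brain voxels.  ``column_mean`` restores the
    original (normalized, un-centered) data exactly.
    """

    data: np.ndarray  # (2*n_subjects, n_voxels), voxel-mean-centered
    subject_ids: list[str]
    conditions: tuple[str, str]
    column_mean: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise InputError("scan matrix must be 2-D")
        if self.data.shape[0] != 2 * len(self.subject_ids):
            raise InputError("expected exactly 2 rows (conditions) per subject")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def uncentered(self) -> np.ndarray:
        return self.data + self.column_mean

    def condition_indicator(self) -> np.ndarray:
        """-1 for the first condition, +1 for the second, per row."""
        return np.tile([-1.0, 1.0], self.n_subjects)


@dataclass
class OrtModel:
    """Fitted components and the selected unit-norm voxel pattern."""

    components: np.ndarray      # (n_pcs, n_voxels), orthonormal rows
    eigenvalues: np.ndarray     # variance per component across scans
    selected: tuple[int, ...]   # 0-based indices of the winning subset
    subset_weights: np.ndarray  # combination weights within the subset
    pattern: np.ndarray         # unit-norm voxel weights
    aic_table: dict[tuple[int, ...], float] = field(default_factory=dict)
    column_mean: np.ndarray | None = None

    def project(self, scans: np.ndarray) -> np.ndarray:
        """Expression of (already normalized) scans on the pattern.

        Scans are re-centered with the training column means so held-out
        groups are projected consistently.
        """
        scans = np.atleast_2d(np.asarray(scans, dtype=float))
        if self.column_mean is not None:
            scans = scans - self.column_mean
        return scans @ self.pattern


@dataclass
class NodalExpression:
    """Per-scan pattern expression, z-scored across all scans."""

    frame: pd.DataFrame  # columns: subject_id, group, condition, expression, z

    def delta(self) -> pd.DataFrame:
        """Per-subject z(second) - z(first)."""
        wide = self.frame.pivot(index="subject_id", columns="condition", values="z")
        first, second = list(dict.fromkeys(self.frame["condition"]))[:2]
        out = self.frame.drop_duplicates("subject_id").set_index("subject_id")[["group"]]
        out["delta_expression"] = wide[second] - wide[first]
        return out.reset_index()


@dataclass
class OrtInference:
    ordinal_statistic: int
    n_subjects: int
    permutation_p: float | None = None
    n_permutations: int = 0
    voxel_p: np.ndarray | None = None
    significant: np.ndarray | None = None
    signed_weights: np.ndarray | None = None
    n_bootstrap: int = 0
    seed: int | None = None


def build_scan_matrix(subjects: list[tuple[str, VolumeImage, VolumeImage]],
                      brain_mask: np.ndarray,
                      conditions: tuple[str, str] = ("F1", "F3")) -> ScanMatrix:
    """Normalize, flatten over the mask and voxel-wise center paired scans.

    ``subjects`` holds (subject_id, first-condition volume,
    second-condition volume) triples; each volume is normalized to its
    in-brain mean (consistent with the ROI stage) before flattening.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not subjects:
        raise InputError("no subjects")
    rows = []
    ids = []
    for sid, first, second in subjects:
        if first is None or second is None:
            raise InputError(f"subject {sid} is missing one condition")
        for vol in (first, second):
            norm = normalize_to_brain_mean(vol, brain_mask)
            rows.append(norm.voxels[brain_mask])
        ids.append(sid)
    data = np.vstack(rows)
    column_mean = data.mean(axis=0)
    return ScanMatrix(data=data - column_mean, subject_ids=ids,
                      conditions=conditions, column_mean=column_mean,
                      brain_mask=brain_mask)


def ordinal_statistic(expressions: np.ndarray) -> int:
    """Number of subjects whose expression increases across conditions.

    ``expressions`` is the per-row projection of a ScanMatrix (subject-
    major, condition order first/second).
    """
    expressions = np.asarray(expressions, dtype=float)
    pairs = expressions.reshape(-1, 2)
    return int(np.sum(pairs[:, 1] > pairs[:, 0]))


def fit_ort(matrix: ScanMatrix, max_pcs: int = 5) -> OrtModel:
    """PCA + AIC subset selection for the ordinal-trend pattern.

    Components are extracted from the subject-and-condition centered
    matrix (per-subject mean scans removed on top of the voxel-mean
    centering).  Candidate subsets are single components and pairs among the first
    ``max_pcs``; within a subset the combination weights are the least-
    squares fit of scan scores to the condition indicator; subsets are
    scored by AIC = m ln(RSS/m) + 2k where RSS is the residual of that
    indicator reconstruction (m scans, k subset size; subject intercepts
    vanish identically because the centered scores are pair-
    antisymmetric).  Scoring the indicator reconstruction rather than the
    raw expression keeps the criterion invariant to expression scale,
    which is what makes selection prefer condition-tracking components
    over low-variance noise ones.  The winning pattern is unit-norm and
    oriented so the majority of subjects increase.
    """
    if matrix.n_subjects < 3:
        raise InputError("need at least 3 subjects")
    # subject-and-condition centering: removing each subject's mean scan
    # strips between-subject variance so components describe within-
    # subject (condition) change
    pairs = matrix.data.reshape(matrix.n_subjects, 2, -1)
    within = (pairs - pairs.mean(axis=1, keepdims=True)).reshape(matrix.data.shape)
    u, s, vt = np.linalg.svd(within, full_matrices=False)
    usable = s > max(s[0], 1e-300) * 1e-10 if s.size else np.array([], dtype=bool)
    if not np.any(usable):
        raise FitError("rank-deficient scan matrix: no usable components")
    u, s, vt = u[:, usable], s[usable], vt[usable]
    n_pcs = int(min(max_pcs, s.size))
    scores = u[:, :n_pcs] * s[:n_pcs]          # scan-by-component expressions
    indicator = matrix.condition_indicator()
    m = matrix.data.shape[0]

    candidates = [(i,) for i in range(n_pcs)]
    candidates += list(itertools.combinations(range(n_pcs), 2))
    aic_table: dict[tuple[int, ...], float] = {}
    best_subset, best_aic, best_w = None, np.inf, None
    for subset in candidates:
        sub_scores = scores[:, list(subset)]
        w, *_ = np.linalg.lstsq(sub_scores, indicator, rcond=None)
        resid = indicator - sub_scores @ w
        rss = float(resid @ resid)
        k = len(subset)
        aic = m * np.log(max(rss, 1e-300) / m) + 2 * k
        aic_table[subset] = float(aic)
        if aic < best_aic:
            best_aic, best_subset, best_w = aic, subset, w

    pattern = vt[list(best_subset)].T @ best_w
    norm = np.linalg.norm(pattern)
    if norm == 0:
        raise FitError("degenerate pattern with zero norm")
    pattern = pattern / norm
    expr = matrix.data @ pattern
    stat = ordinal_statistic(expr)
    if stat < matrix.n_subjects - stat:  # orient: majority of subjects increase
        pattern = -pattern
        best_w = -best_w
    return OrtModel(components=vt, eigenvalues=(s**2) / (m - 1),
                    selected=tuple(best_subset), subset_weights=best_w,
                    pattern=pattern, aic_table=aic_table,
                    column_mean=matrix.column_mean)


def permutation_test(matrix: ScanMatrix, n_iter: int = 500, seed: int = 0,
                     max_pcs: int = 5) -> tuple[float, OrtModel]:
    """Within-subject condition-flip permutation test of the ordinal trend.

    Per iteration each subject's two rows are swapped independently with
    probability 1/2, the full model is refit and the ordinal statistic
    recomputed; p = (1 + #{permuted >= observed}) / (1 + n_iter).
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    model = fit_ort(matrix, max_pcs=max_pcs)
    observed = ordinal_statistic(matrix.data @ model.pattern)
    n = matrix.n_subjects
    count = 0
    for _ in range(n_iter):
        flips = rng.random(n) < 0.5
        perm = matrix.data.reshape(n, 2, -1).copy()
        perm[flips] = perm[flips][:, ::-1, :]
        perm_matrix = ScanMatrix(data=perm.reshape(2 * n, -1),
                                 subject_ids=matrix.subject_ids,
                                 conditions=matrix.conditions,
                                 column_mean=matrix.column_mean,
                                 brain_mask=matrix.brain_mask)
        perm_model = fit_ort(perm_matrix, max_pcs=max_pcs)
        perm_stat = ordinal_statistic(perm_matrix.data @ perm_model.pattern)
        if perm_stat >= observed:
            count += 1
    return (1 + count) / (1 + n_iter), model


def bootstrap_voxel_pmap(matrix: ScanMatrix, n_boot: int = 500, seed: int = 0,
                         max_pcs: int = 5, alpha: float = 0.05) -> OrtInference:
    """Subject-level bootstrap reliability of the pattern's voxel weights.

    Subjects are resampled with replacement (both scans travel together);
    the pattern is refit per replicate and sign-aligned to the observed
    pattern; the one-tailed voxel p is the add-one fraction of replicates
    whose weight crosses zero against the observed sign.
    """
    if n_boot < 1:
        raise InputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    model = fit_ort(matrix, max_pcs=max_pcs)
    observed = model.pattern
    n = matrix.n_subjects
    raw = matrix.uncentered().reshape(n, 2, -1)
    crossings = np.zeros(observed.size)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot = raw[idx].reshape(2 * n, -1)
        col_mean = boot.mean(axis=0)
        boot_matrix = ScanMatrix(data=boot - col_mean,
                                 subject_ids=[f"b{i}" for i in range(n)],
                                 conditions=matrix.conditions,
                                 column_mean=col_mean,
                                 brain_mask=matrix.brain_mask)
        boot_model = fit_ort(boot_matrix, max_pcs=max_pcs)
        bp = boot_model.pattern
        if bp @ observed < 0:
            bp = -bp
        crossings += (np.sign(bp) != np.sign(observed)) | (observed == 0)
    voxel_p = (1.0 + crossings) / (1.0 + n_boot)
    significant = voxel_p < alpha
    expr = matrix.data @ observed
    return OrtInference(ordinal_statistic=ordinal_statistic(expr),
                        n_subjects=n, voxel_p=voxel_p, significant=significant,
                        signed_weights=observed.copy(), n_bootstrap=n_boot,
                        seed=seed)


def nodal_expression_delta(model: OrtModel,
                           scans: list[tuple[str, str, VolumeImage, VolumeImage]],
                           brain_mask: np.ndarray,
                           conditions: tuple[str, str] = ("F1", "F3")
                           ) -> NodalExpression:
    """Project scans from all groups onto a fitted pattern.

    ``scans`` holds (subject_id, group, first, second) tuples, typically
    including groups held out of the fit.  Expressions are z-scored
    across all projected scans; ``NodalExpression.delta`` gives
    z(second) - z(first) per subject.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    rows = []
    for sid, group, first, second in scans:
        for cond, vol in zip(conditions, (first, second)):
            norm = normalize_to_brain_mean(vol, brain_mask)
            expr = float(model.project(norm.voxels[brain_mask])[0])
            rows.append({"subject_id": sid, "group": group,
                         "condition": cond, "expression": expr})
    frame = pd.DataFrame(rows)
    sd = frame["expression"].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        frame["z"] = 0.0
    else:
        frame["z"] = (frame["expression"] - frame["expression"].mean()) / sd
    return NodalExpression(frame=frame)
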