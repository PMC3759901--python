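"""Within-patient temporal permutation test for the filtered-feature count.

The observed statistic is the number of distinct features passing the
MAID filter over all post-baseline comparisons.  The null is generated
by independently shuffling each patient's time-point labels (identity
permutation allowed) and re-running the complete scoring and filtering
chain — MA transform, spread-curve fit, cutoff — on every permuted
relabeling.  The empirical p-value is the fraction of permutations whose
count meets or exceeds the observed count.

Because the spread curve depends only on the unordered sample pair
(the spread of M is invariant to the sign of M and A is symmetric) and
MAID scores are antisymmetric under swapping treated and baseline, the
scores of all possible relabelings can be precomputed once per patient
from the C(T, 2) unordered sample pairs; each permutation then reduces
to tensor lookups.  This is an exact reformulation, not an
approximation, and is verified against the direct recompute path in the
test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import StudyDesign
from .errors import ConfigurationError
from .maid import (
    Comparison,
    compute_scores,
    filter_features,
    fit_maid_curve,
    ma_transform,
    maid_score,
)
from .matrix import LongitudinalMatrix


@dataclass
class PermutationNull:
    """Null distribution of filtered-feature counts under label shuffling."""

    n_perm: int
    null_counts: np.ndarray
    observed_count: int
    mean_null: float
    p_emp: float
    seed: int
    plus_one: bool = False

    def __post_init__(self) -> None:
        assert len(self.null_counts) == self.n_perm


def permute_design(design: StudyDesign, rng: np.random.Generator) -> StudyDesign:
    """Shuffle each patient's time-point labels independently and uniformly.

    Platform and card assignments are untouched; the permuted object is
    itself a valid study design (same patients, same label set).
    """
    tps = list(design.time_points)
    new_map: dict[str, tuple[str, str]] = {}
    for patient in design.patients:
        perm = rng.permutation(len(tps))
        relabel = {tps[i]: tps[perm[i]] for i in range(len(tps))}
        for col, (pat, tp) in design.sample_map.items():
            if pat == patient:
                new_map[col] = (pat, relabel[tp])
    for col, key in design.sample_map.items():
        if col not in new_map:  # samples of patients outside the design list
            new_map[col] = key
    return design.with_sample_map(new_map)


# ---------------------------------------------------------------------------
# cached scorer


class _PairScoreCache:
    """MAID scores for every ordered sample pair of every patient.

    ``scores[patient][(i, j)]`` holds the per-feature score vector for
    "time-slot j versus baseline-slot i", where slots index the design's
    time-point order.  Only unordered pairs are fitted; the swapped
    orientation is the negation.
    """

    def __init__(
        self,
        matrix: LongitudinalMatrix,
        floor: float,
        n_bins: int = 20,
        robust_spread: bool = False,
    ) -> None:
        design = matrix.design
        self.design = design
        self.time_points = list(design.time_points)
        self.patients = list(design.patients)
        n_tp = len(self.time_points)
        n_feat = len(matrix.features)
        self.features = matrix.features
        # tensor (patient, T, T, feature): score of (treated=tp_j, baseline=tp_i)
        self.tensor = np.zeros((len(self.patients), n_tp, n_tp, n_feat))
        for pi, patient in enumerate(self.patients):
            for i, j in itertools.combinations(range(n_tp), 2):
                comp: Comparison = (self.time_points[j], self.time_points[i])
                pair = ma_transform(matrix, patient, comp, floor)
                curve = fit_maid_curve(pair, n_bins=n_bins, robust_spread=robust_spread)
                s = maid_score(pair, curve)
                self.tensor[pi, i, j, :] = s
                self.tensor[pi, j, i, :] = -s

    def count(self, slot_of_label: np.ndarray, C: float, k: int) -> int:
        """Filtered-feature union count for one joint relabeling.

        ``slot_of_label[p, t]`` gives the physical sample slot carrying
        time-point label t for patient p (label 0 is the baseline).
        """
        n_pat, n_tp = slot_of_label.shape
        passed_up = None
        passed_down = None
        pat_idx = np.arange(n_pat)
        base = slot_of_label[:, 0]
        for t in range(1, n_tp):
            treat = slot_of_label[:, t]
            # (patients, features) score block for this comparison
            block = self.tensor[pat_idx, base, treat, :]
            up = (block > C).sum(axis=0) >= k
            down = (block < -C).sum(axis=0) >= k
            passed_up = up if passed_up is None else (passed_up | up)
            passed_down = down if passed_down is None else (passed_down | down)
        return int((passed_up | passed_down).sum())


def permutation_test(
    matrix: LongitudinalMatrix,
    C: float,
    k: int,
    n_perm: int = 1000,
    seed: int = 0,
    floor: float | None = None,
    n_bins: int = 20,
    robust_spread: bool = False,
    plus_one: bool = False,
) -> PermutationNull:
    """Empirical significance of the observed filtered-feature count.

    Runs ``n_perm`` independent joint relabelings (uniform over each
    patient's time-label orderings), recomputes the full MAID filter for
    each, and reports the fraction of null counts ≥ the observed count.
    With ``plus_one`` the add-one estimator (r+1)/(n+1) is used instead.
    Fully reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if floor is None:
        floor = float(np.nanmin(matrix.values.to_numpy())) or 1e-12
    matrix.design.require_complete()
    cache = _PairScoreCache(matrix, floor=floor, n_bins=n_bins, robust_spread=robust_spread)
    n_pat = len(cache.patients)
    n_tp = len(cache.time_points)

    identity = np.tile(np.arange(n_tp), (n_pat, 1))
    observed = cache.count(identity, C, k)

    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        slots = np.stack([rng.permutation(n_tp) for _ in range(n_pat)])
        null_counts[b] = cache.count(slots, C, k)

    exceed = int((null_counts >= observed).sum())
    p_emp = (exceed + 1) / (n_perm + 1) if plus_one else exceed / n_perm
    return PermutationNull(
        n_perm=n_perm,
        null_counts=null_counts,
        observed_count=observed,
        mean_null=float(null_counts.mean()),
        p_emp=float(p_emp),
        seed=seed,
        plus_one=plus_one,
    )


def exhaustive_null(
    matrix: LongitudinalMatrix,
    C: float,
    k: int,
    floor: float | None = None,
    n_bins: int = 20,
) -> tuple[np.ndarray, int, float]:
    """Exact null by enumerating every joint relabeling (small designs only).

    Returns (all counts, observed count, exact p).  With T time points
    and P patients this enumerates (T!)^P relabelings — feasible for the
    oracle-scale instances it exists for.
    """
    if floor is None:
        floor = float(np.nanmin(matrix.values.to_numpy())) or 1e-12
    cache = _PairScoreCache(matrix, floor=floor, n_bins=n_bins)
    n_pat = len(cache.patients)
    n_tp = len(cache.time_points)
    identity = np.tile(np.arange(n_tp), (n_pat, 1))
    observed = cache.count(identity, C, k)
    perms = list(itertools.permutations(range(n_tp)))
    counts = []
    for combo in itertools.product(perms, repeat=n_pat):
        counts.append(cache.count(np.asarray(combo), C, k))
    counts = np.asarray(counts)
    p_exact = float((counts >= observed).mean())
    return counts, observed, p_exact


def direct_count(
    matrix: LongitudinalMatrix,
    design: StudyDesign,
    C: float,
    k: int,
    floor: float,
    n_bins: int = 20,
) -> int:
    """Filtered-feature count via the direct (uncached) scoring path.

    Used to verify that the pair-cache reformulation is exact.
    """
    relabeled = matrix.with_design(design)
    scores = compute_scores(relabeled, floor=floor, n_bins=n_bins)
    return filter_features(scores, C, k).union_count
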