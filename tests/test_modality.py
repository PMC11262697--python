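"""Migration-modality machinery: the dip statistic against an
independent LP minimax oracle, Monte-Carlo calibration of the sequential
tests, and the classification of prescribed trajectories."""

import numpy as np
import pytest
from scipy.optimize import linprog

from capnet._dip import (N_BINS, _rotate_modal_center, dip_from_counts,
                         kuiper_from_counts)
from capnet.fixtures import synthetic_trajectory
from capnet.morphometrics import (HEAD_AND_TAIL, ISOTROPIC, ONE_DIRECTION,
                                  classify_modality, direction_histogram)


# -- LP oracle: dip = min over unimodal CDFs of the sup-distance ---------

def _case_feasible_lp(x, c, m, e, t, atom):
    """Is a unimodal CDF within sup-distance e of the binned ECDF
    feasible, with mode at knot t (atom allowed) or in gap (t, t+1)?"""
    nv = m + 1 if atom else m
    iL = m
    A, b = [], []

    def row():
        return [0.0] * nv

    for i in range(m):
        targets = [c[i + 1], c[i]]
        if atom and i == t:
            targets = [c[i + 1]]
        for tg in targets:
            r = row(); r[i] = 1; A.append(r); b.append(tg + e)
            r = row(); r[i] = -1; A.append(r); b.append(-(tg - e))
    if atom:
        r = row(); r[iL] = 1; A.append(r); b.append(c[t] + e)
        r = row(); r[iL] = -1; A.append(r); b.append(-(c[t] - e))
        seq_l = [(x[i], i) for i in range(t)] + [(x[t], iL)]
        seq_r = [(x[i], i) for i in range(t, m)]
    else:
        seq_l = [(x[i], i) for i in range(t + 1)]
        seq_r = [(x[i], i) for i in range(t + 1, m)]
    order = [v for _, v in seq_l] + [v for _, v in seq_r]
    for a1, a2 in zip(order[:-1], order[1:]):
        r = row(); r[a1] = 1; r[a2] = -1; A.append(r); b.append(0.0)

    def shape(seq, sign):
        for (x0, v0), (x1, v1), (x2, v2) in zip(seq[:-2], seq[1:-1], seq[2:]):
            r = row()
            r[v2] += 1.0 / (x2 - x1)
            r[v1] -= 1.0 / (x2 - x1)
            r[v1] -= 1.0 / (x1 - x0)
            r[v0] += 1.0 / (x1 - x0)
            A.append([-sign * v for v in r])
            b.append(0.0)

    shape(seq_l, +1.0)
    shape(seq_r, -1.0)
    res = linprog(np.zeros(nv), A_ub=np.array(A), b_ub=np.array(b),
                  bounds=[(0, 1)] * nv, method="highs")
    return res.status == 0


def dip_lp_oracle(counts, tol=1e-5):
    counts = np.asarray(counts)
    nz = np.nonzero(counts)[0]
    m = len(nz)
    if m <= 1:
        return 0.0
    x = nz.astype(float)
    c = np.zeros(m + 1)
    c[1:] = np.cumsum(counts[nz]) / counts.sum()

    def feasible(e):
        return any(_case_feasible_lp(x, c, m, e, t, True) for t in range(m)) \
            or any(_case_feasible_lp(x, c, m, e, t, False)
                   for t in range(m - 1))

    lo, hi = 0.0, 0.5
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def _random_counts(rng, kind, n):
    if kind == "uniform":
        raw = rng.integers(0, 12, n)
    elif kind == "unimodal":
        raw = np.clip(rng.normal(6, 1.5, n).astype(int), 0, 11)
    else:
        mix = np.concatenate([rng.normal(3, 1, n // 2),
                              rng.normal(9, 1, n - n // 2)])
        raw = np.clip(mix.astype(int), 0, 11)
    return np.bincount(raw, minlength=12).astype(np.int64)


@pytest.mark.parametrize("kind", ["uniform", "unimodal", "bimodal"])
def test_dip_matches_lp_oracle(kind):
    rng = np.random.default_rng(hash(kind) % 2 ** 31)
    for _ in range(8):
        counts = _rotate_modal_center(_random_counts(rng, kind,
                                                     int(rng.integers(4, 40))))
        assert dip_from_counts(counts) == pytest.approx(
            dip_lp_oracle(counts), abs=3e-4)


def test_dip_degenerate_cases():
    one_bin = np.zeros(12, dtype=np.int64)
    one_bin[6] = 60
    assert dip_from_counts(one_bin) == pytest.approx(0.0, abs=1e-6)
    assert dip_from_counts(np.zeros(12, dtype=np.int64)) == 0.0
    # opposed half-half sample is maximally dippy for its atom size
    opp = np.zeros(12, dtype=np.int64)
    opp[3] = opp[9] = 30
    assert dip_from_counts(_rotate_modal_center(opp)) == pytest.approx(0.25,
                                                                      abs=1e-3)


def test_kuiper_rotation_invariant():
    rng = np.random.default_rng(0)
    counts = _random_counts(rng, "unimodal", 60)
    v0 = kuiper_from_counts(counts)
    for s in (1, 5, 11):
        assert kuiper_from_counts(np.roll(counts, s)) == pytest.approx(v0, abs=1e-12)
    assert kuiper_from_counts(np.full(12, 5, dtype=np.int64)) <= 1e-12


def test_direction_histogram_binning():
    steps = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0],
                      [np.cos(np.pi / 6), np.sin(np.pi / 6)], [0.0, 0.0]])
    counts = direction_histogram(steps)
    assert counts.sum() == 4  # zero step excluded
    assert counts[0] == 1 and counts[3] == 1 and counts[6] == 1
    assert counts[1] == 1  # 30 degrees


class TestClassification:
    def test_one_bin_is_one_direction(self, null_tables):
        steps = synthetic_trajectory("one_direction", seed=3)
        assert classify_modality(steps, tables=null_tables) == ONE_DIRECTION

    def test_opposed_bins_is_head_and_tail(self, null_tables):
        steps = synthetic_trajectory("head_and_tail", seed=3)
        assert classify_modality(steps, tables=null_tables) == HEAD_AND_TAIL

    def test_few_steps_isotropic_by_convention(self, null_tables):
        steps = synthetic_trajectory("one_direction", n_steps=60, seed=3,
                                     zero_fraction=0.9)
        assert classify_modality(steps, tables=null_tables) == ISOTROPIC

    def test_type_one_error_calibration(self, null_tables):
        """Uniform walkers are labelled non-isotropic at a rate close to
        alpha1 = 0.1 (Monte-Carlo binomial bound, 600 replicates)."""
        n = 600
        rejections = sum(
            classify_modality(synthetic_trajectory("isotropic", seed=s),
                              tables=null_tables) != ISOTROPIC
            for s in range(n))
        rate = rejections / n
        # discreteness makes the achievable level conservative; accept
        # [0.05, 0.145] around the nominal 0.1
        assert 0.05 <= rate <= 0.145
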