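"""Independent reference implementations used only to check the package.

Each oracle is written from the definition, in a different style from the
library code (pure Python, enumeration, closed forms), so that agreement is
evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import math
from itertools import groupby


def local_max_runs(y) -> list[int]:
    """Earliest index of each local-maximum run (pure-Python groupby).

    A run of equal values is a maximum when strictly greater than the
    values on both sides; the right end of the series needs only its inner
    side, the first sample is never a peak.
    """
    runs = []
    i = 0
    for val, grp in groupby(y):
        n = len(list(grp))
        runs.append((i, i + n - 1, val))
        i += n
    reps = []
    for k, (lo, hi, val) in enumerate(runs):
        left_ok = k > 0 and runs[k - 1][2] < val
        right_ok = k == len(runs) - 1 or runs[k + 1][2] < val
        if left_ok and right_ok and not (lo == 0):
            reps.append(lo)
    return reps


def brute_force_pulses(y, min_increment_pct=25.0, min_value=0.02
                       ) -> list[tuple[int, int]]:
    """All (nadir index, peak index) pulse calls by explicit search.

    From the current start position, try every local maximum in order with
    the minimum over the samples since the start as its nadir; the first
    qualifying pair is a call, and the search restarts after its peak.
    """
    y = list(map(float, y))
    reps = local_max_runs(y)
    calls = []
    start = 0
    while start < len(y) - 1:
        found = None
        for p in reps:
            if p <= start:
                continue
            window = y[start:p]
            nadir = min(window)
            nidx = start + window.index(nadir)
            if (nadir >= min_value and nadir > 0
                    and 100.0 * (y[p] - nadir) / nadir > min_increment_pct):
                found = (nidx, p)
                break
        if found is None:
            break
        calls.append(found)
        start = found[1] + 1
    return calls


def permutation_mannwhitney_p(a, b) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group splits.

    Returns (U for group a, p).  Valid only without ties.
    """
    a, b = list(a), list(b)
    na = len(a)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}

    def u_of(group):
        r = sum(ranks[v] for v in group)
        return r - len(group) * (len(group) + 1) / 2

    u_obs = u_of(a)
    us = [sum(idx_ranks) - na * (na + 1) / 2
          for idx_ranks in (
              [ranks[pooled[i]] for i in comb]
              for comb in itertools.combinations(range(len(pooled)), na))]
    n_total = len(us)
    lo = sum(1 for u in us if u <= u_obs)
    hi = sum(1 for u in us if u >= u_obs)
    p = min(1.0, 2.0 * min(lo, hi) / n_total)
    return u_obs, p


def gaussian_fwhm_overlap(sigma1: float, sigma2: float, shift: float) -> float:
    """Closed-form overlap of the half-max supports of two unit Gaussians
    whose peaks are ``shift`` apart."""
    h1 = sigma1 * math.sqrt(2.0 * math.log(2.0))
    h2 = sigma2 * math.sqrt(2.0 * math.log(2.0))
    left = max(-h1, shift - h2)
    right = min(h1, shift + h2)
    return max(0.0, right - left)
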