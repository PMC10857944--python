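"""Spatiotemporal leader-follower time-interval analysis.

For a directed species pair (leader, follower) the statistic is the median,
pooled over stations, of the waiting time from each follower contact back to
the most recent preceding leader contact *at the same station*.  Because the
clock only starts once the leader has been at that specific camera, the
statistic is spatiotemporal: it reacts both to where the two species overlap
and to when they arrive.

The null hypothesis — the leader has no influence on the follower — is
simulated by re-timestamping every follower contact: a calendar date drawn
uniformly from the dates its station was deployed, and a time of day drawn
from the follower's own diel activity pattern (by default the empirical
distribution of its observed contact clock-times, pooled across stations).
Leader contacts and per-station follower counts are untouched, so the null
preserves spatial overlap and diel activity while destroying any temporal
coupling to the leader.  Repeating this ``reps`` times (1000 by default)
gives a null distribution of medians; with Q the proportion of null medians
greater than the observed one,

    p = min(Q, 1 - Q) * 2

is the two-sided Monte-Carlo p-value.  Null medians exactly equal to the
observed median count one half toward Q.  A positive percent difference,
100 * (median(null) - observed) / median(null), means the observed waiting
time is shorter than expected — attraction; negative means avoidance.

Randomized follower events are deliberately *not* re-passed through the
independence filter: the null permutes the filtered contacts as-is, so
per-station counts are conserved by construction.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .io import SurveyDataset

__all__ = [
    "DirectedPair",
    "ActivityPattern",
    "IntervalTestResult",
    "TimeIntervalTest",
    "activity_pattern",
    "leader_follower_intervals",
    "observed_median",
    "randomize_follower",
    "null_distribution",
    "interval_test",
    "run_all_pairs",
]

_STATION_STRIDE = 1.0e7  # hours; far beyond any survey span


@dataclasses.dataclass(frozen=True)
class DirectedPair:
    """An ordered species pair: the leader starts the clock, the follower stops it."""

    leader: str
    follower: str

    def __post_init__(self):
        if self.leader == self.follower:
            raise ValueError("leader and follower must differ")

    def __str__(self) -> str:
        return f"{self.leader} -> {self.follower}"


@dataclasses.dataclass(frozen=True)
class ActivityPattern:
    """A species' diel activity: the clock-times (hours in [0, 24)) of its contacts."""

    species: str
    clock_times: np.ndarray

    def __post_init__(self):
        ct = np.asarray(self.clock_times, dtype=float)
        if ct.size and ((ct < 0) | (ct >= 24)).any():
            raise ValueError("clock times must lie in [0, 24)")
        object.__setattr__(self, "clock_times", ct)

    def sample(self, n: int, rng: np.random.Generator, estimator: str = "empirical",
               kde_kappa: float = 50.0) -> np.ndarray:
        """Draw ``n`` times of day.

        ``empirical`` resamples the observed clock-times with replacement
        (assumption-free, the default); ``vonmises_kde`` smooths each
        observation with a circular von Mises kernel of concentration
        ``kde_kappa`` before sampling.
        """
        if self.clock_times.size == 0:
            raise ValueError("empty activity pattern")
        base = rng.choice(self.clock_times, size=n, replace=True)
        if estimator == "empirical":
            return base
        if estimator == "vonmises_kde":
            ang = base / 24.0 * 2 * np.pi
            jit = rng.vonmises(ang, kde_kappa)
            return (jit % (2 * np.pi)) / (2 * np.pi) * 24.0
        raise ValueError("estimator must be 'empirical' or 'vonmises_kde'")


def activity_pattern(contacts: pd.DataFrame, species: str) -> ActivityPattern:
    """Site-pooled diel activity pattern of one species' contacts."""
    ts = contacts.loc[contacts["species"] == species, "timestamp"]
    clock = (
        ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    ).to_numpy(dtype=float)
    return ActivityPattern(species=species, clock_times=clock)


# --------------------------------------------------------------------------
# internal engine on float hours
# --------------------------------------------------------------------------


def _epoch(dataset: SurveyDataset) -> pd.Timestamp:
    return dataset.deployments["start"].min().normalize()


def _to_hours(ts: pd.Series, epoch: pd.Timestamp) -> np.ndarray:
    return ((ts - epoch) / pd.Timedelta(hours=1)).to_numpy(dtype=float)


class _PairEngine:
    """Precomputed arrays for one (leader, follower) pair on one survey.

    Times are float hours since the survey epoch; stations are integer codes.
    Leader positions are encoded as ``code * STRIDE + time`` into one sorted
    array so a single searchsorted finds, for every follower event, the most
    recent preceding leader event at the same station.
    """

    def __init__(self, contacts, dataset, pair, pairing_mode="most_recent",
                 max_lag_hours=None, activity_estimator="empirical", kde_kappa=50.0):
        if pairing_mode not in ("most_recent", "first_after_leader"):
            raise ValueError("pairing_mode must be 'most_recent' or 'first_after_leader'")
        self.pair = pair
        self.pairing_mode = pairing_mode
        self.max_lag_hours = max_lag_hours
        self.activity_estimator = activity_estimator
        self.kde_kappa = kde_kappa

        self.epoch = _epoch(dataset)
        dep = dataset.deployments
        stations = dep["station_id"].to_numpy()
        self.station_code = {s: i for i, s in enumerate(stations)}
        start_h = _to_hours(dep["start"], self.epoch)
        end_h = _to_hours(dep["end"], self.epoch)
        self.start_h, self.end_h = start_h, end_h
        # calendar dates intersecting [start, end): first midnight and count
        self.first_date_h = np.floor(start_h / 24.0) * 24.0
        self.n_dates = (
            np.floor((end_h - 1e-9) / 24.0) - np.floor(start_h / 24.0)
        ).astype(np.int64) + 1

        lead = contacts.loc[contacts["species"] == pair.leader]
        foll = contacts.loc[contacts["species"] == pair.follower]
        self.lead_code = lead["station_id"].map(self.station_code).to_numpy(dtype=np.int64)
        self.lead_h = _to_hours(lead["timestamp"], self.epoch)
        self.foll_code = foll["station_id"].map(self.station_code).to_numpy(dtype=np.int64)
        self.foll_h = _to_hours(foll["timestamp"], self.epoch)

        key = self.lead_code * _STATION_STRIDE + self.lead_h
        order = np.argsort(key, kind="stable")
        self.lead_key_sorted = key[order]
        self.lead_code_sorted = self.lead_code[order]
        self.lead_h_sorted = self.lead_h[order]

        self.activity = ActivityPattern(
            pair.follower,
            (self.foll_h % 24.0),
        )

    # -- interval extraction -------------------------------------------------
    def intervals(self, foll_h: np.ndarray) -> np.ndarray:
        if self.pairing_mode == "most_recent":
            out = self._intervals_most_recent(foll_h)
        else:
            out = self._intervals_first_after(foll_h)
        if self.max_lag_hours is not None:
            out = out[out <= self.max_lag_hours]
        return out

    def _intervals_most_recent(self, foll_h: np.ndarray) -> np.ndarray:
        if self.lead_key_sorted.size == 0 or foll_h.size == 0:
            return np.empty(0)
        fkey = self.foll_code * _STATION_STRIDE + foll_h
        pos = np.searchsorted(self.lead_key_sorted, fkey, side="left") - 1
        ok = pos >= 0
        ok[ok] &= self.lead_code_sorted[pos[ok]] == self.foll_code[ok]
        return foll_h[ok] - self.lead_h_sorted[pos[ok]]

    def _intervals_first_after(self, foll_h: np.ndarray) -> np.ndarray:
        # per leader event: time to the first follower event after it
        if self.lead_key_sorted.size == 0 or foll_h.size == 0:
            return np.empty(0)
        fkey = np.sort(self.foll_code * _STATION_STRIDE + foll_h)
        pos = np.searchsorted(fkey, self.lead_key_sorted, side="right")
        ok = pos < fkey.size
        fcode = np.floor(fkey[pos[ok]] / _STATION_STRIDE).astype(np.int64)
        ok2 = fcode == self.lead_code_sorted[ok]
        ftime = fkey[pos[ok]][ok2] - fcode[ok2] * _STATION_STRIDE
        return ftime - self.lead_h_sorted[ok][ok2]

    # -- null resampling -----------------------------------------------------
    def randomized_follower_hours(self, rng: np.random.Generator) -> np.ndarray:
        """New follower times: uniform deployment date + diel clock-time.

        A draw landing outside the station's [start, end) window (possible on
        partial first/last days) is redrawn.
        """
        n = self.foll_h.size
        codes = self.foll_code
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            c = codes[todo]
            day = rng.integers(0, self.n_dates[c])
            clock = self.activity.sample(
                todo.size, rng, self.activity_estimator, self.kde_kappa
            )
            t = self.first_date_h[c] + 24.0 * day + clock
            good = (t >= self.start_h[c]) & (t < self.end_h[c])
            out[todo[good]] = t[good]
            todo = todo[~good]
        return out


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def leader_follower_intervals(
    contacts: pd.DataFrame,
    pair: DirectedPair,
    dataset: SurveyDataset,
    pairing_mode: str = "most_recent",
    max_lag_hours: float | None = None,
) -> np.ndarray:
    """Observed leader-to-follower waiting times (hours), pooled over stations."""
    eng = _PairEngine(contacts, dataset, pair, pairing_mode, max_lag_hours)
    return np.sort(eng.intervals(eng.foll_h))


def observed_median(intervals: np.ndarray) -> float | None:
    """Median waiting time; None when there are no intervals (untestable pair)."""
    intervals = np.asarray(intervals, dtype=float)
    if intervals.size == 0:
        return None
    return float(np.median(intervals))


def randomize_follower(
    contacts: pd.DataFrame,
    follower: str,
    activity: ActivityPattern,
    dataset: SurveyDataset,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """One null replicate of the contact table: follower re-timestamped.

    Every follower contact keeps its station but gets a random deployment
    date and an activity-pattern time of day; all other rows are unchanged.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    other = contacts.loc[contacts["species"] != follower]
    foll = contacts.loc[contacts["species"] == follower]
    if foll.empty:
        return contacts.copy()
    # borrow the engine's sampler with a throwaway leader
    pair = DirectedPair(leader="\x00none", follower=follower)
    eng = _PairEngine(contacts, dataset, pair)
    eng.activity = activity
    hours = eng.randomized_follower_hours(rng)
    epoch = _epoch(dataset)
    new_foll = foll.copy()
    new_foll["timestamp"] = epoch + pd.to_timedelta(
        np.round(hours * 3600.0), unit="s"
    )
    out = pd.concat([other, new_foll], ignore_index=True)
    return out.sort_values(["station_id", "species", "timestamp"]).reset_index(drop=True)


@dataclasses.dataclass
class IntervalTestResult:
    """Outcome of the randomization test for one directed pair.

    ``p_two_sided`` is None for untestable pairs (no observed intervals or no
    valid replicates); ``unreliable`` is set when more than 20% of replicates
    produced no intervals.  ``pct_difference > 0`` means the observed median
    is shorter than the null expectation — the attraction direction.
    """

    pair: DirectedPair
    observed_median: float | None
    null_medians: np.ndarray
    Q: float | None
    p_two_sided: float | None
    pct_difference: float | None
    band_95: tuple[float, float] | None
    n_intervals_observed: int
    n_invalid_replicates: int
    reps: int
    seed: int | None
    pairing_mode: str
    unreliable: bool = False
    untestable_reason: str | None = None

    @property
    def testable(self) -> bool:
        return self.p_two_sided is not None

    @property
    def significant(self) -> bool:
        return self.testable and self.p_two_sided < 0.05

    def p_display(self) -> str:
        if self.p_two_sided is None:
            return "NA"
        if self.p_two_sided == 0.0:
            n_valid = self.reps - self.n_invalid_replicates
            return f"< {1.0 / max(n_valid, 1):.4g}"
        return f"{self.p_two_sided:.4g}"

    def summary(self) -> str:
        head = f"Interval test {self.pair} ({self.pairing_mode}, reps={self.reps})"
        if not self.testable:
            return f"{head}\n  untestable: {self.untestable_reason}"
        lo, hi = self.band_95
        direction = "attraction" if self.pct_difference > 0 else "avoidance"
        lines = [
            head,
            f"  observed median: {self.observed_median:.2f} h over "
            f"{self.n_intervals_observed} intervals",
            f"  null median: {float(np.median(self.null_medians)):.2f} h "
            f"(95% band {lo:.2f} - {hi:.2f})",
            f"  pct difference: {self.pct_difference:+.1f}% ({direction} direction)",
            f"  Q = {self.Q:.3f}   p = {self.p_display()}",
        ]
        if self.unreliable:
            lines.append(
                f"  WARNING: {self.n_invalid_replicates} invalid replicates (> 20%)"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "leader": self.pair.leader,
            "follower": self.pair.follower,
            "observed_median_hours": self.observed_median,
            "Q": self.Q,
            "p": self.p_two_sided,
            "pct_difference": self.pct_difference,
            "band_95": list(self.band_95) if self.band_95 else None,
            "n_intervals": self.n_intervals_observed,
            "n_invalid_replicates": self.n_invalid_replicates,
            "reps": self.reps,
            "seed": self.seed,
            "pairing_mode": self.pairing_mode,
            "unreliable": self.unreliable,
            "untestable_reason": self.untestable_reason,
        }


class TimeIntervalTest:
    """Randomization test of spatiotemporal attraction/avoidance for one pair.

    Statsmodels-style: construct from data, then :meth:`fit` runs the
    resampling and returns an :class:`IntervalTestResult`.

    Parameters
    ----------
    contacts : DataFrame
        Independent contact table (post independence-filter).
    dataset : SurveyDataset
        Supplies deployment windows for the date resampling.
    pair : DirectedPair or (leader, follower) tuple
    pairing_mode : {'most_recent', 'first_after_leader'}
        How follower events are matched to leader events; the default pairs
        each follower with the latest prior leader event at its station.
    max_lag_hours : float, optional
        Discard intervals longer than this (sensitivity analysis); default no cap.
    """

    def __init__(self, contacts, dataset, pair, pairing_mode="most_recent",
                 max_lag_hours=None, activity_estimator="empirical", kde_kappa=50.0):
        if not isinstance(pair, DirectedPair):
            pair = DirectedPair(*pair)
        self.pair = pair
        self._engine = _PairEngine(
            contacts, dataset, pair, pairing_mode, max_lag_hours,
            activity_estimator, kde_kappa,
        )

    def fit(self, reps: int = 1000, seed=None) -> IntervalTestResult:
        """Run the randomization and assemble the result.

        ``seed`` may be an int, a ``numpy.random.SeedSequence`` or ``None``.
        """
        eng = self._engine
        obs = eng.intervals(eng.foll_h)
        obs_median = observed_median(obs)

        base = dict(
            pair=self.pair, reps=reps,
            seed=seed if isinstance(seed, (int, np.integer)) else None,
            pairing_mode=eng.pairing_mode,
        )
        if obs_median is None or eng.activity.clock_times.size == 0:
            return IntervalTestResult(
                observed_median=obs_median, null_medians=np.empty(0), Q=None,
                p_two_sided=None, pct_difference=None, band_95=None,
                n_intervals_observed=int(obs.size), n_invalid_replicates=0,
                untestable_reason="no observed leader-follower intervals",
                **base,
            )

        rng = np.random.default_rng(seed)
        null_medians = np.full(reps, np.nan)
        for r in range(reps):
            sim = eng.intervals(eng.randomized_follower_hours(rng))
            if sim.size:
                null_medians[r] = np.median(sim)
        valid = null_medians[np.isfinite(null_medians)]
        n_invalid = reps - valid.size
        if valid.size == 0:
            return IntervalTestResult(
                observed_median=obs_median, null_medians=null_medians, Q=None,
                p_two_sided=None, pct_difference=None, band_95=None,
                n_intervals_observed=int(obs.size), n_invalid_replicates=n_invalid,
                untestable_reason="all null replicates produced no intervals",
                **base,
            )
        # ties with the observed median count one half toward Q
        q = (np.sum(valid > obs_median) + 0.5 * np.sum(valid == obs_median)) / valid.size
        p = min(min(q, 1.0 - q) * 2.0, 1.0)
        null_med = float(np.median(valid))
        pct = 100.0 * (null_med - obs_median) / null_med if null_med != 0 else np.nan
        lo, hi = np.percentile(valid, [2.5, 97.5])
        return IntervalTestResult(
            observed_median=obs_median, null_medians=null_medians, Q=float(q),
            p_two_sided=float(p), pct_difference=float(pct),
            band_95=(float(lo), float(hi)), n_intervals_observed=int(obs.size),
            n_invalid_replicates=int(n_invalid),
            unreliable=n_invalid > 0.2 * reps,
            **base,
        )


def null_distribution(
    contacts, pair, dataset, reps: int = 1000, seed=None, **kwargs
) -> np.ndarray:
    """Null medians only (NaN marks replicates with no intervals)."""
    test = TimeIntervalTest(contacts, dataset, pair, **kwargs)
    return test.fit(reps=reps, seed=seed).null_medians


def interval_test(
    contacts, pair, dataset, reps: int = 1000, seed=None, **kwargs
) -> IntervalTestResult:
    """One-call functional form of :class:`TimeIntervalTest`."""
    return TimeIntervalTest(contacts, dataset, pair, **kwargs).fit(reps=reps, seed=seed)


def run_all_pairs(
    contacts: pd.DataFrame,
    dataset: SurveyDataset,
    species: list[str],
    reps: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> list[IntervalTestResult]:
    """All ordered pairs of ``species`` (4 species give 12 results).

    Each pair runs on its own deterministic RNG substream derived from the
    master seed and the pair's position in the sorted pair list, so results
    do not depend on execution order.
    """
    pairs = [
        DirectedPair(a, b) for a, b in itertools.permutations(species, 2)
    ]
    results = []
    for i, pair in enumerate(pairs):
        sub = np.random.SeedSequence([0 if seed is None else int(seed), i])
        res = TimeIntervalTest(contacts, dataset, pair, **kwargs).fit(
            reps=reps, seed=sub
        )
        res.seed = seed
        results.append(res)
    return results
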