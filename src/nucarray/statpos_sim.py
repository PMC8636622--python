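"""Hard-sphere simulation of statistical nucleosome positioning.

Models nucleosome arrays that arise purely from excluded-volume packing
against a well-positioned +1 nucleosome, with no active spacing: an
ensemble of DNA fragments each receives one Gaussian-positioned +1 near one
end, then further nucleosomes (146 bp hard spheres) are deposited by random
sequential adsorption — a random fragment, a random position, accepted only
if the footprint does not overlap an existing one — until a target fraction
of the DNA is covered.  Histone exchange is emulated by churn cycles:
a fixed fraction of non-+1 nucleosomes dissociates and is re-deposited by
the same rule.  The dyad composite of the resulting ensemble shows the
characteristic decaying oscillations of statistical positioning against a
barrier.

Occupancies are kept below the 1-D random-sequential-adsorption jamming
limit (~74.8%, Rényi's parking constant), where deposition would stall.
"""

from __future__ import annotations

import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .arraystats import smooth
from .metagene import CompositeProfile

__all__ = ["SimConfig", "SimResult", "run_sim", "sim_composite",
           "peak_positions", "plus2_shift", "validate_hard_sphere",
           "write_sim_result"]

_RNG_CHUNK = 8192  # placement attempts drawn per batch of random numbers


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the statistical-positioning simulation.

    Defaults follow the histone-depletion scenario: 10,000 fragments of
    2,000-2,500 bp, a 146 bp footprint, the +1 dyad drawn from
    Normal(73, 25) so its footprint abuts the fragment start, deposition to
    51% occupancy, then nine cycles in which 20% of nucleosomes dissociate
    and are re-placed.
    """

    n_fragments: int = 10_000
    frag_len_min: int = 2000
    frag_len_max: int = 2500
    footprint: int = 146
    plus1_sigma: float = 25.0
    plus1_mean_offset: int = 73
    target_occupancy: float = 0.51
    churn_fraction: float = 0.20
    churn_cycles: int = 9
    seed: int = 0
    max_rejections: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0.0 < self.target_occupancy < 0.74):
            raise ValueError("target_occupancy must lie in (0, 0.74), below "
                             "the 1-D jamming regime")
        if self.footprint > self.frag_len_min:
            raise ValueError("footprint must fit on the shortest fragment")
        if self.frag_len_min > self.frag_len_max or self.n_fragments < 1:
            raise ValueError("invalid fragment ensemble parameters")


@dataclass
class SimResult:
    """Nucleosome configurations on the fragment ensemble.

    dyads[i] is the sorted list of dyad positions (bp from fragment start)
    on fragment i; plus1[i] the fragment's +1 dyad (always present).
    achieved_occupancy[0] is the occupancy after the initial deposition,
    entries 1..churn_cycles after each churn re-placement.
    """

    config: SimConfig
    fragment_lengths: np.ndarray
    dyads: list[list[int]]
    plus1: list[int]
    achieved_occupancy: list[float]

    @property
    def final_occupancy(self) -> float:
        return self.achieved_occupancy[-1]

    @property
    def n_nucleosomes(self) -> int:
        return sum(len(d) for d in self.dyads)

    def occupancy(self) -> float:
        return self.n_nucleosomes * self.config.footprint / \
            float(self.fragment_lengths.sum())


class SaturationError(RuntimeError):
    """Raised when deposition cannot reach the target occupancy."""


def _half(footprint: int) -> int:
    return footprint // 2


class _Placer:
    """Random sequential adsorption over the fragment ensemble, with
    chunked random-number draws for speed."""

    def __init__(self, lengths: np.ndarray, dyads: list[list[int]],
                 footprint: int, rng: np.random.Generator,
                 max_rejections: int):
        self.lengths = lengths
        self.dyads = dyads
        self.footprint = footprint
        self.half = _half(footprint)
        self.rng = rng
        self.max_rejections = max_rejections
        self.n = len(lengths)
        # dyad position is uniform on [half, len - (footprint - half)]
        self.n_positions = lengths - footprint + 1
        self._frags = np.empty(0, dtype=np.int64)
        self._us = np.empty(0)
        self._i = _RNG_CHUNK

    def _refill(self) -> None:
        self._frags = self.rng.integers(0, self.n, size=_RNG_CHUNK)
        self._us = self.rng.random(_RNG_CHUNK)
        self._i = 0

    def place(self, count: int) -> None:
        """Deposit ``count`` nucleosomes at random non-overlapping positions."""
        placed = 0
        rejections = 0
        fp, half = self.footprint, self.half
        while placed < count:
            if self._i >= _RNG_CHUNK:
                self._refill()
            fi = self._frags[self._i]
            d = half + int(self._us[self._i] * self.n_positions[fi])
            self._i += 1
            lst = self.dyads[fi]
            j = bisect_left(lst, d)
            if (j > 0 and d - lst[j - 1] < fp) or \
               (j < len(lst) and lst[j] - d < fp):
                rejections += 1
                if rejections > self.max_rejections:
                    raise SaturationError(
                        f"{rejections} consecutive rejected placements; "
                        "ensemble too crowded to reach the target occupancy")
                continue
            lst.insert(j, d)
            placed += 1
            rejections = 0


def run_sim(config: SimConfig = SimConfig()) -> SimResult:
    """Run the full deposition + churn protocol.

    Stages draw from independent named random streams split off the master
    seed (fragment lengths; +1 draws; deposition; churn selection), so each
    stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_len, rng_plus1, rng_place, rng_churn = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    lengths = rng_len.integers(config.frag_len_min, config.frag_len_max + 1,
                               size=config.n_fragments)
    total_bp = float(lengths.sum())
    half = _half(config.footprint)
    fp = config.footprint

    # +1 nucleosomes: Gaussian near the fragment start, redrawn until the
    # footprint fits on the fragment
    plus1: list[int] = []
    for L in lengths:
        hi = int(L) - (fp - half)
        while True:
            d = int(round(rng_plus1.normal(config.plus1_mean_offset,
                                           config.plus1_sigma)))
            if half <= d <= hi:
                break
        plus1.append(d)
    dyads: list[list[int]] = [[d] for d in plus1]

    placer = _Placer(lengths, dyads, fp, rng_place, config.max_rejections)

    def occupancy() -> float:
        return sum(len(d) for d in dyads) * fp / total_bp

    n_target = int(np.ceil(config.target_occupancy * total_bp / fp))
    n_now = config.n_fragments
    if n_target > n_now:
        placer.place(n_target - n_now)
    achieved = [occupancy()]

    plus1_set = [set([p]) for p in plus1]  # +1 dyads never dissociate
    for _ in range(config.churn_cycles):
        n_total = sum(len(d) for d in dyads)
        n_remove = int(config.churn_fraction * n_total)
        n_remove = min(n_remove, n_total - config.n_fragments)
        if n_remove > 0:
            movable = [(fi, d) for fi, lst in enumerate(dyads)
                       for d in lst if d not in plus1_set[fi]]
            pick = rng_churn.choice(len(movable), size=n_remove, replace=False)
            for k in pick:
                fi, d = movable[k]
                lst = dyads[fi]
                lst.pop(bisect_left(lst, d))
            placer.place(n_remove)
        achieved.append(occupancy())

    return SimResult(config=config, fragment_lengths=lengths, dyads=dyads,
                     plus1=plus1, achieved_occupancy=achieved)


def validate_hard_sphere(result: SimResult) -> bool:
    """Exhaustive check: on every fragment all dyad pairs are >= footprint
    apart and every footprint lies within the fragment.  Raises on violation."""
    fp = result.config.footprint
    half = _half(fp)
    for fi, (lst, L) in enumerate(zip(result.dyads,
                                      result.fragment_lengths)):
        arr = np.asarray(lst)
        if len(arr) and (arr.min() < half or arr.max() > int(L) - (fp - half)):
            raise AssertionError(f"fragment {fi}: footprint out of bounds")
        diff = np.abs(arr[:, None] - arr[None, :])
        np.fill_diagonal(diff, fp)
        if (diff < fp).any():
            raise AssertionError(f"fragment {fi}: overlapping footprints")
        if result.plus1[fi] not in lst:
            raise AssertionError(f"fragment {fi}: +1 nucleosome lost")
    return True


def sim_composite(result: SimResult, max_pos: int | None = None
                  ) -> CompositeProfile:
    """Dyad-position histogram (1 bp bins from the fragment start) divided
    per position by the number of fragments long enough to contain it."""
    if max_pos is None:
        max_pos = int(result.config.frag_len_min)
    all_dyads = np.concatenate([np.asarray(d) for d in result.dyads])
    counts = np.bincount(all_dyads[all_dyads < max_pos],
                         minlength=max_pos).astype(np.float64)
    sorted_len = np.sort(result.fragment_lengths)
    pos = np.arange(max_pos)
    n_cover = len(sorted_len) - np.searchsorted(sorted_len, pos, side="right")
    n_cover = np.maximum(n_cover, 1)
    return CompositeProfile(pos, counts / n_cover,
                            n_genes=result.config.n_fragments)


def peak_positions(profile: CompositeProfile, n_peaks: int,
                   min_separation: int = 100,
                   smooth_window: int = 31) -> list[int]:
    """First ``n_peaks`` local maxima of the boxcar-smoothed profile in
    increasing position, keeping the higher of any two maxima closer than
    ``min_separation`` bp."""
    y = smooth(profile.values, smooth_window)
    if np.ptp(y) == 0:
        raise ValueError("profile is constant; no peaks")
    idx, _ = find_peaks(y, distance=min_separation)
    if len(idx) < n_peaks:
        raise ValueError(f"found only {len(idx)} peaks, need {n_peaks}")
    return [int(profile.positions[i]) for i in idx[:n_peaks]]


def plus2_shift(config_low: SimConfig, config_high: SimConfig,
                replicates: int = 3, seed: int = 0) -> float:
    """Absolute difference (bp) between the mean +2 peak positions of two
    occupancy conditions, each run ``replicates`` times with derived seeds."""
    means = []
    for cond, cfg in enumerate((config_low, config_high)):
        plus2 = []
        for r in range(replicates):
            child = int(np.random.SeedSequence(
                seed, spawn_key=(cond, r)).generate_state(1)[0] % 2**31)
            res = run_sim(replace(cfg, seed=child))
            prof = sim_composite(res, max_pos=min(1000, cfg.frag_len_min))
            plus2.append(peak_positions(prof, n_peaks=2)[1])
        means.append(float(np.mean(plus2)))
    return abs(means[0] - means[1])


def write_sim_result(result: SimResult, prefix: str | Path) -> None:
    """Write dyads as TSV (fragment_id, dyad) plus a JSON run manifest."""
    prefix = Path(prefix)
    with open(f"{prefix}_dyads.tsv", "w") as fh:
        fh.write("fragment_id\tdyad\n")
        for fi, lst in enumerate(result.dyads):
            for d in lst:
                fh.write(f"{fi}\t{d}\n")
    manifest = {
        "config": {k: (v if not isinstance(v, np.integer) else int(v))
                   for k, v in vars(result.config).items()},
        "achieved_occupancy": result.achieved_occupancy,
        "n_nucleosomes": int(result.n_nucleosomes),
    }
    with open(f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
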