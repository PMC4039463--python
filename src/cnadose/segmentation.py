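"""Copy-number segmentation of marker-level log2 ratios.

A five-state Gaussian hidden Markov model (states 0-4 = homozygous deletion,
one-copy loss, diploid, one-copy gain, amplification) is decoded with the
Viterbi algorithm per chromosome arm. Maximal runs of constant state become
segments; boundaries fall at the midpoint between flanking markers of
differing state, so the union of segments covers the marker span exactly.

Downstream filters retain copy-number alterations (CNAs): non-diploid
segments with a minimum marker count, a minimum physical length, and a
bounded overlap with germline constitutive CNVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_STATES = 5
DIPLOID_STATE = 2

#: Default emission means on the log2-ratio scale: log2(CN/2) with a -2.0
#: floor for the zero-copy state.
DEFAULT_STATE_MEANS = (-2.0, -1.0, 0.0, np.log2(3 / 2), 1.0)

SEGMENT_COLUMNS = ["sample", "arm", "start", "end", "state", "n_markers", "length"]


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the five-state segmentation HMM.

    ``self_transition`` is the per-marker probability of staying in the
    current state; the remainder is spread uniformly over the other states
    (no genomic-distance scaling). Transitions are homogeneous.
    """

    state_means: tuple[float, ...] = DEFAULT_STATE_MEANS
    emission_sd: float = 0.25
    self_transition: float = 0.999
    #: width of the running-mean smoother applied before decoding (odd;
    #: 1 disables smoothing). Raw per-marker decoding leaves segment
    #: boundaries noise-limited; a short running mean trades resolution
    #: below the window width for a large variance reduction.
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if len(self.state_means) != N_STATES:
            raise ValueError("exactly 5 state means required")
        if self.emission_sd <= 0:
            raise ValueError("emission_sd must be positive")
        if not 0 < self.self_transition < 1:
            raise ValueError("self_transition must lie in (0, 1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")

    @property
    def transition_matrix(self) -> np.ndarray:
        off = (1.0 - self.self_transition) / (N_STATES - 1)
        mat = np.full((N_STATES, N_STATES), off)
        np.fill_diagonal(mat, self.self_transition)
        return mat

    @property
    def start_probs(self) -> np.ndarray:
        return np.full(N_STATES, 1.0 / N_STATES)


@dataclass
class MarkerTrack:
    """Per-sample marker positions and log2 copy ratios, keyed by arm."""

    sample_id: str
    arms: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arm, (pos, lr) in self.arms.items():
            pos = np.asarray(pos)
            lr = np.asarray(lr, dtype=float)
            if pos.shape != lr.shape:
                raise ValueError(f"{arm}: positions and ratios differ in length")
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{arm}: positions must be strictly increasing")
            if not np.all(np.isfinite(lr)):
                raise ValueError(f"{arm}: non-finite log2 ratios")
            self.arms[arm] = (pos, lr)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None) -> "MarkerTrack":
        """Build from a long table with columns sample, arm, pos, log2_ratio."""
        if sample_id is not None:
            df = df[df["sample"] == sample_id]
        elif df["sample"].nunique() != 1:
            raise ValueError("frame holds several samples; pass sample_id")
        else:
            sample_id = df["sample"].iloc[0]
        arms = {}
        for arm, sub in df.groupby("arm", sort=False):
            sub = sub.sort_values("pos")
            arms[str(arm)] = (sub["pos"].to_numpy(), sub["log2_ratio"].to_numpy(float))
        return cls(sample_id=str(sample_id), arms=arms)

    @property
    def n_markers(self) -> int:
        return sum(len(pos) for pos, _ in self.arms.values())


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a standard dependency
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not a or not callable(a[0]) else a[0]


@_njit(cache=False)
def _viterbi_kernel(loglik, log_trans, log_start):  # pragma: no cover - jitted
    n, k = loglik.shape
    delta = log_start + loglik[0]
    psi = np.zeros((n, k), dtype=np.int8)
    for t in range(1, n):
        new = np.empty(k)
        for j in range(k):
            best, arg = -np.inf, 0
            for i in range(k):
                v = delta[i] + log_trans[i, j]
                if v > best:
                    best, arg = v, i
            new[j] = best + loglik[t, j]
            psi[t, j] = arg
        delta = new
    path = np.empty(n, dtype=np.int64)
    path[-1] = np.argmax(delta)
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


def viterbi_path(log2_ratios: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable state sequence for one arm (log-space Viterbi)."""
    x = np.asarray(log2_ratios, dtype=float)
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    means = np.asarray(params.state_means)
    sd = params.emission_sd
    # Gaussian log density up to a shared constant
    loglik = -0.5 * ((x[:, None] - means[None, :]) / sd) ** 2
    log_trans = np.log(params.transition_matrix)
    log_start = np.log(params.start_probs)
    return _viterbi_kernel(loglik, log_trans, log_start)


def viterbi_loglik(log2_ratios: np.ndarray, states: np.ndarray,
                   params: HMMParams) -> float:
    """Joint log probability (up to the shared Gaussian constant) of a path."""
    x = np.asarray(log2_ratios, dtype=float)
    states = np.asarray(states, dtype=int)
    means = np.asarray(params.state_means)
    ll = float(np.log(params.start_probs[states[0]]))
    ll += float(np.sum(-0.5 * ((x - means[states]) / params.emission_sd) ** 2))
    if len(states) > 1:
        log_trans = np.log(params.transition_matrix)
        ll += float(np.sum(log_trans[states[:-1], states[1:]]))
    return ll


def _runs_to_segments(pos: np.ndarray, path: np.ndarray, sample: str,
                      arm: str) -> list[tuple]:
    """Cut maximal constant-state runs at inter-marker midpoints."""
    change = np.flatnonzero(np.diff(path)) + 1  # index of first marker of a new run
    starts_idx = np.concatenate(([0], change))
    ends_idx = np.concatenate((change, [len(path)]))
    rows = []
    for i0, i1 in zip(starts_idx, ends_idx):
        start = int(pos[0]) if i0 == 0 else int((pos[i0 - 1] + pos[i0]) // 2)
        end = int(pos[-1]) + 1 if i1 == len(path) else int((pos[i1 - 1] + pos[i1]) // 2)
        rows.append((sample, arm, start, end, int(path[i0]), int(i1 - i0), end - start))
    return rows


def viterbi_segment(track: MarkerTrack, params: HMMParams | None = None) -> pd.DataFrame:
    """Segment one sample's marker track into constant-copy-number segments.

    Returns a frame with columns sample, arm, start, end, state, n_markers,
    length. Adjacent segments within an arm always carry different states.
    """
    from scipy.ndimage import uniform_filter1d

    params = params or HMMParams()
    rows: list[tuple] = []
    for arm in sorted(track.arms):
        pos, lr = track.arms[arm]
        if len(pos) == 0:
            continue
        if params.smooth_window > 1 and len(lr) > 1:
            lr = uniform_filter1d(np.asarray(lr, float),
                                  params.smooth_window, mode="nearest")
        path = viterbi_path(lr, params)
        rows.extend(_runs_to_segments(pos, path, track.sample_id, arm))
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _union_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge possibly overlapping [start, end) intervals into a disjoint union."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    order = np.argsort(intervals[:, 0])
    merged = [list(intervals[order[0]])]
    for s, e in intervals[order[1:]]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _covered_bases(start: int, end: int, union: np.ndarray) -> int:
    if len(union) == 0:
        return 0
    lo = np.minimum(np.maximum(union[:, 0], start), end)
    hi = np.minimum(union[:, 1], end)
    return int(np.maximum(hi - lo, 0).sum())


def cnv_overlap_fraction(segments: pd.DataFrame,
                         germline_cnvs: pd.DataFrame | None) -> np.ndarray:
    """Fraction of each segment's bases inside the union of germline CNVs."""
    if germline_cnvs is None or len(germline_cnvs) == 0:
        return np.zeros(len(segments))
    unions = {
        arm: _union_intervals(sub[["start", "end"]].to_numpy())
        for arm, sub in germline_cnvs.groupby("arm")
    }
    frac = np.zeros(len(segments))
    for i, row in enumerate(segments.itertuples(index=False)):
        union = unions.get(row.arm)
        if union is not None:
            frac[i] = _covered_bases(row.start, row.end, union) / row.length
    return frac


def filter_cnas(segments: pd.DataFrame,
                germline_cnvs: pd.DataFrame | None = None,
                min_markers: int = 50,
                min_length: int = 500_000,
                max_cnv_overlap: float = 0.5) -> pd.DataFrame:
    """Retain copy-number alterations passing the call filters.

    Keeps non-diploid segments with ``n_markers >= min_markers``, physical
    length ``>= min_length`` bp and germline-CNV overlap ``<= max_cnv_overlap``
    (boundary inclusive). Idempotent by construction.
    """
    if min_markers < 0 or min_length < 0 or max_cnv_overlap < 0:
        raise ValueError("thresholds must be non-negative")
    segments = segments.copy()
    segments["cnv_overlap"] = cnv_overlap_fraction(segments, germline_cnvs)
    keep = (
        (segments["state"] != DIPLOID_STATE)
        & (segments["n_markers"] >= min_markers)
        & (segments["length"] >= min_length)
        & (segments["cnv_overlap"] <= max_cnv_overlap)
    )
    return segments[keep].reset_index(drop=True)


def collapse_cn4(segments: pd.DataFrame) -> pd.DataFrame:
    """Pool the amplification state with single-copy gain (4 -> 3).

    Adjacent same-state segments (contiguous within a sample and arm) are
    merged, with marker counts summed and length recomputed.
    """
    seg = segments.copy()
    seg["state"] = seg["state"].replace(4, 3)
    out_rows = []
    for (sample, arm), sub in seg.groupby(["sample", "arm"], sort=False):
        sub = sub.sort_values("start")
        cur = None
        for row in sub.itertuples(index=False):
            if (cur is not None and cur["state"] == row.state
                    and cur["end"] == row.start):
                cur["end"] = row.end
                cur["n_markers"] += row.n_markers
            else:
                if cur is not None:
                    out_rows.append(cur)
                cur = {"sample": sample, "arm": arm, "start": row.start,
                       "end": row.end, "state": row.state,
                       "n_markers": row.n_markers}
        if cur is not None:
            out_rows.append(cur)
    out = pd.DataFrame(out_rows, columns=SEGMENT_COLUMNS[:-1])
    out["length"] = out["end"] - out["start"]
    extra = [c for c in segments.columns if c not in out.columns]
    for c in extra:  # carry filter annotations only when nothing merged
        if len(out) == len(segments):
            out[c] = segments.sort_values(["sample", "arm", "start"])[c].to_numpy()
    return out.reset_index(drop=True)


def _direction(state: int) -> int:
    return 0 if state == DIPLOID_STATE else (1 if state > DIPLOID_STATE else -1)


def platform_concordance(a: pd.DataFrame, b: pd.DataFrame,
                         size_bins: list[int] | np.ndarray) -> pd.DataFrame:
    """Cross-platform agreement of CNA calls, stratified by segment size.

    A segment of ``a`` agrees when at least half of its bases are covered by
    same-direction (gain/loss) segments of ``b`` on the same arm. Returns one
    row per size bin plus an ``overall`` row with columns bin_low, bin_high,
    n_segments, agreement_pct. The Spearman correlation of bin midpoint vs
    agreement is attached as ``.attrs['spearman_r']`` / ``['spearman_p']``.
    """
    from scipy import stats

    size_bins = np.asarray(size_bins)
    if len(a) == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_segments",
                                     "agreement_pct"])
    b_unions: dict[tuple[str, int], np.ndarray] = {}
    for (arm, ), sub in b.groupby(["arm"]):
        for sign in (-1, 1):
            ivals = sub[[_direction(s) == sign for s in sub["state"]]]
            b_unions[(arm, sign)] = _union_intervals(ivals[["start", "end"]].to_numpy())
    agree = np.zeros(len(a), dtype=bool)
    for i, row in enumerate(a.itertuples(index=False)):
        sign = _direction(row.state)
        union = b_unions.get((row.arm, sign), np.empty((0, 2)))
        agree[i] = _covered_bases(row.start, row.end, union) >= 0.5 * row.length
    lengths = a["length"].to_numpy()
    bin_idx = np.digitize(lengths, size_bins)
    edges = np.concatenate(([0], size_bins, [np.inf]))
    rows = []
    mids, pcts = [], []
    for k in range(len(edges) - 1):
        mask = bin_idx == k
        if mask.sum() == 0:
            continue
        pct = 100.0 * agree[mask].mean()
        rows.append((edges[k], edges[k + 1], int(mask.sum()), pct))
        if np.isfinite(edges[k + 1]):
            mids.append((edges[k] + edges[k + 1]) / 2)
        else:
            mids.append(edges[k] * 1.5)
        pcts.append(pct)
    rows.append(("overall", "", len(a), 100.0 * agree.mean()))
    out = pd.DataFrame(rows, columns=["bin_low", "bin_high", "n_segments",
                                      "agreement_pct"])
    if len(mids) >= 2 and len(set(pcts)) > 1:
        r, p = stats.spearmanr(mids, pcts)
        out.attrs["spearman_r"], out.attrs["spearman_p"] = float(r), float(p)
    return out
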