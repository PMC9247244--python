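"""Windowing and leakage-free train/test splitting.

A cleaned series plus the coach's sparse label events become fixed-length
labeled windows: each window spans 50 consecutive samples (5 s at 10 Hz)
of the 12-channel stream, and its target is the most recent coach label
at the window's last sample (last-label-carried-forward).  Samples before
the first label are unlabeled and excluded.

Splitting follows the contiguous-block scheme used for sparse,
non-uniform labels: random contiguous sample segments of at least 50
samples are removed from the stream to form the test pool until test
windows are roughly 1/4 of the training windows.  Training windows that
contain *any* test sample are discarded (not reassigned), which makes the
no-leakage guarantee absolute, and draws that unbalance the class ratio
between the pools are rejected.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulate import ImuSeries, LabelEvent

UNLABELED = -1
DEFAULT_WINDOW = 50


def propagate_labels(series: ImuSeries, events: list[LabelEvent]) -> np.ndarray:
    """Per-sample binary state by last-label-carried-forward.

    Each sample takes the state of the most recent event at or before its
    timestamp; samples before the first event are marked ``UNLABELED``
    (-1).  Raises if there are no events at all.
    """
    if not events:
        raise ValueError("no label events to propagate")
    ev = sorted(events, key=lambda e: e.timestamp)
    times = np.array([e.timestamp for e in ev])
    states = np.array([e.state for e in ev], dtype=np.int8)
    idx = np.searchsorted(times, series.timestamps, side="right") - 1
    out = np.where(idx >= 0, states[np.clip(idx, 0, None)], np.int8(UNLABELED))
    return out.astype(np.int8)


@dataclass
class WindowSet:
    """Fixed-length labeled windows with provenance.

    ``inputs`` is (M, window, 12) float32; ``targets`` is the binary state
    at each window's last sample; ``start_indices`` are the sample indices
    of each window's first sample in the cleaned series (used by the
    splitter's overlap bookkeeping).
    """

    inputs: np.ndarray
    targets: np.ndarray
    end_timestamps: np.ndarray
    player_id: str
    stride: int
    window: int = DEFAULT_WINDOW
    start_indices: np.ndarray = None
    n_samples: int = 0  # length of the underlying cleaned series

    def __post_init__(self):
        if self.inputs.ndim != 3 or self.inputs.shape[1] != self.window:
            raise ValueError("inputs must be (M, window, channels)")
        if not np.isin(self.targets, (0, 1)).all():
            raise ValueError("targets must be binary")
        if len(self.end_timestamps) > 1 and np.any(np.diff(self.end_timestamps) <= 0):
            raise ValueError("end_timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.targets)

    def save(self, prefix) -> None:
        """Persist as an .npz container with a JSON sidecar."""
        np.savez(
            f"{prefix}.npz",
            inputs=self.inputs,
            targets=self.targets,
            end_timestamps=self.end_timestamps,
            start_indices=self.start_indices,
        )
        with open(f"{prefix}.json", "w") as fh:
            json.dump(
                {
                    "player_id": self.player_id,
                    "stride": self.stride,
                    "window": self.window,
                    "n_windows": len(self),
                    "n_samples": self.n_samples,
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, prefix) -> "WindowSet":
        arrays = np.load(f"{prefix}.npz")
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        return cls(
            inputs=arrays["inputs"],
            targets=arrays["targets"],
            end_timestamps=arrays["end_timestamps"],
            player_id=meta["player_id"],
            stride=meta["stride"],
            window=meta["window"],
            start_indices=arrays["start_indices"],
            n_samples=meta["n_samples"],
        )


def make_windows(
    series: ImuSeries,
    states: np.ndarray,
    window: int = DEFAULT_WINDOW,
    stride: int = 1,
) -> WindowSet:
    """Cut a labeled series into fixed-length windows.

    Windows containing any unlabeled sample are dropped; with labels
    starting at sample 0 the count is ``floor((N - window)/stride) + 1``.
    A series shorter than one window yields an empty set with a warning.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    states = np.asarray(states)
    n = len(series)
    labeled = np.flatnonzero(states != UNLABELED)
    first = int(labeled[0]) if len(labeled) else n
    starts = np.arange(first, n - window + 1, stride, dtype=np.int64)
    if len(starts) == 0:
        warnings.warn("series shorter than one window; empty WindowSet")
        return WindowSet(
            inputs=np.empty((0, window, series.channels.shape[1]), np.float32),
            targets=np.empty(0, np.int8),
            end_timestamps=np.empty(0),
            player_id=series.player_id,
            stride=stride,
            window=window,
            start_indices=starts,
            n_samples=n,
        )
    ends = starts + window - 1
    # gather windows (strided view, then one copy)
    sview = np.lib.stride_tricks.sliding_window_view(series.channels, window, axis=0)
    inputs = np.ascontiguousarray(sview[starts].transpose(0, 2, 1)).astype(np.float32)
    return WindowSet(
        inputs=inputs,
        targets=states[ends].astype(np.int8),
        end_timestamps=series.timestamps[ends],
        player_id=series.player_id,
        stride=stride,
        window=window,
        start_indices=starts,
        n_samples=n,
    )


class SplitError(RuntimeError):
    """Raised when no valid split satisfies the constraints."""


@dataclass
class SplitPlan:
    """Test segments and derived window indices for one replicate."""

    test_segments: list[tuple[int, int]]  # half-open sample ranges
    train_window_ids: np.ndarray
    test_window_ids: np.ndarray
    seed: int

    def validate(self, windows: WindowSet, *, min_segment: int = DEFAULT_WINDOW,
                 ratio_band: tuple[float, float] = (0.18, 0.32),
                 balance_tol: float = 0.15) -> None:
        """Machine-check every invariant; raises AssertionError on violation."""
        starts = windows.start_indices
        w = windows.window
        test_mask = np.zeros(windows.n_samples, bool)
        for a, b in self.test_segments:
            assert b - a >= min_segment, "test segment shorter than minimum"
            test_mask[a:b] = True
        for wid in self.train_window_ids:
            s = starts[wid]
            assert not test_mask[s : s + w].any(), "training window touches test sample"
        for wid in self.test_window_ids:
            s = starts[wid]
            assert test_mask[s : s + w].all(), "test window not fully inside test pool"
        assert len(np.intersect1d(self.train_window_ids, self.test_window_ids)) == 0
        ratio = len(self.test_window_ids) / max(len(self.train_window_ids), 1)
        assert ratio_band[0] <= ratio <= ratio_band[1], f"test/train ratio {ratio:.3f} out of band"
        tr = windows.targets[self.train_window_ids].mean()
        te = windows.targets[self.test_window_ids].mean()
        assert abs(tr - te) <= balance_tol, "class ratio mismatch between pools"

    def to_json(self) -> str:
        return json.dumps(
            {
                "test_segments": [list(map(int, s)) for s in self.test_segments],
                "train_window_ids": self.train_window_ids.tolist(),
                "test_window_ids": self.test_window_ids.tolist(),
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            test_segments=[tuple(s) for s in d["test_segments"]],
            train_window_ids=np.array(d["train_window_ids"], dtype=np.int64),
            test_window_ids=np.array(d["test_window_ids"], dtype=np.int64),
            seed=d["seed"],
        )


def _classify_windows(windows: WindowSet, test_mask: np.ndarray):
    """Window ids fully inside / fully outside the test pool."""
    cum = np.concatenate([[0], np.cumsum(test_mask)])
    s = windows.start_indices
    w = windows.window
    covered = cum[s + w] - cum[s]
    test_ids = np.flatnonzero(covered == w)
    train_ids = np.flatnonzero(covered == 0)
    return train_ids, test_ids


def make_splits(
    windows: WindowSet,
    n_replicates: int = 5,
    target_ratio: float = 0.25,
    seed: int = 0,
    *,
    min_segment: int = DEFAULT_WINDOW,
    max_segment: int = 300,
    balance_tol: float = 0.15,
    ratio_band: tuple[float, float] = (0.18, 0.32),
    max_attempts: int = 1000,
) -> list[SplitPlan]:
    """Draw ``n_replicates`` leakage-free contiguous-segment splits.

    Per replicate, random contiguous sample segments (length uniform in
    ``[min_segment, max_segment]``) are moved into the test pool until the
    test/train *window* ratio reaches ``target_ratio``.  Draws that push
    the ratio above the band or that worsen an already-violated class
    balance are rejected; if the pool reaches the target ratio with an
    unbalanced class mix, the segment whose removal best restores balance
    is dropped and drawing continues.  Training windows overlapping any
    test sample are discarded.  All plan invariants are machine-checked
    before returning.
    """
    if len(windows) == 0:
        raise SplitError("empty window set")
    n = windows.n_samples
    lo = int(windows.start_indices[0])
    if n - lo < 2 * min_segment:
        raise SplitError("series too short to split")
    ss = np.random.SeedSequence([int(seed), 0x5B11])

    def _state(test_mask):
        """(train_ids, test_ids, ratio, class-balance difference)."""
        tr, te = _classify_windows(windows, test_mask)
        ratio = len(te) / len(tr) if len(tr) else np.inf
        if len(te) and len(tr):
            diff = abs(float(windows.targets[tr].mean() - windows.targets[te].mean()))
        else:
            diff = np.inf
        return tr, te, ratio, diff

    plans = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        segments: list[tuple[int, int]] = []
        test_mask = np.zeros(n, bool)
        for attempt in range(max_attempts):
            _, _, ratio, diff = _state(test_mask)
            if target_ratio <= ratio <= ratio_band[1] and diff <= balance_tol:
                break
            if ratio >= target_ratio and segments and rng.random() < 0.5:
                # pool large enough but unbalanced: drop the segment whose
                # removal most improves the class balance
                best, best_diff = None, diff
                for k in range(len(segments)):
                    m = test_mask.copy()
                    a, b = segments[k]
                    m[a:b] = False
                    _, _, r2, d2 = _state(m)
                    if d2 < best_diff:
                        best, best_diff = k, d2
                if best is not None:
                    a, b = segments.pop(best)
                    test_mask[a:b] = False
                continue
            # draw a candidate segment
            length = int(rng.integers(min_segment, max_segment + 1))
            if n - length <= lo:
                continue
            a = int(rng.integers(lo, n - length + 1))
            b = a + length
            if test_mask[a:b].any():
                continue  # overlaps an existing test segment
            test_mask[a:b] = True
            _, te2, ratio2, diff2 = _state(test_mask)
            ok = ratio2 <= ratio_band[1] and (
                ratio2 < target_ratio  # still building the pool
                or diff2 <= balance_tol  # satisfies balance outright
                or diff2 < diff  # or at least improves it
            )
            if ok:
                segments.append((a, b))
            else:
                test_mask[a:b] = False
        else:
            _, _, ratio, diff = _state(test_mask)
            violated = (
                "class balance between pools"
                if diff > balance_tol
                else "test/train ratio outside band"
            )
            raise SplitError(
                f"replicate {rep}: no valid split after {max_attempts} attempts "
                f"(violated: {violated})"
            )
        train_ids, test_ids = _classify_windows(windows, test_mask)
        segments.sort()
        plan = SplitPlan(
            test_segments=segments,
            train_window_ids=train_ids,
            test_window_ids=test_ids,
            seed=int(seed),
        )
        plan.validate(
            windows,
            min_segment=min_segment,
            ratio_band=ratio_band,
            balance_tol=balance_tol,
        )
        plans.append(plan)
    return plans
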