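"""Turning averaged component probabilities into integer copy-number calls.

The sampler's primary output is omega_bar, the n x k_max matrix of per-SNP
component probabilities averaged over post-burn-in iterations (zero for
classes that were inactive at an iteration).  Each SNP is assigned the
copy number of its most probable class; exact ties break conservatively
toward the diploid class, then toward the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_model import CopyNumberClass

__all__ = ["ChainResult", "CallSegment", "call_copy_numbers",
           "segment_calls", "expand_segments"]


@dataclass
class ChainResult:
    """Output of one sampler run on one chromosome."""

    omega_bar: np.ndarray  # n x k_max averaged class probabilities
    calls: np.ndarray      # per-SNP integer copy-number labels
    classes: list[CopyNumberClass]
    diagnostics: object    # MoveStats
    k_trace: np.ndarray
    h_trace: np.ndarray


@dataclass(frozen=True)
class CallSegment:
    """Maximal run of a constant copy-number call.

    ``start``/``end`` are half-open SNP indices; genomic positions (1-based,
    inclusive first/last SNP) are carried when available.
    """

    start: int
    end: int
    cn_label: int
    n_snps: int
    start_pos: int | None = None
    end_pos: int | None = None


def call_copy_numbers(omega_bar: np.ndarray,
                      classes: Sequence[CopyNumberClass]) -> np.ndarray:
    """Per-SNP argmax call over the averaged class probabilities.

    Invariant to positive rescaling of rows.  A row of all zeros indicates
    a malformed accumulation and raises.
    """
    omega = np.atleast_2d(np.asarray(omega_bar, dtype=float))
    if omega.shape[1] != len(classes):
        raise ValueError("omega_bar column count does not match classes")
    row_max = omega.max(axis=1)
    if np.any(row_max <= 0):
        bad = int(np.argmax(row_max <= 0))
        raise ValueError(f"probability row {bad} sums to zero")
    # Reorder columns so that np.argmax's first-max rule implements the tie
    # break: diploid class first, then ascending class index.
    order = sorted(range(len(classes)),
                   key=lambda j: (classes[j].cn_label != 2, j))
    labels = np.array([classes[j].cn_label for j in order])
    return labels[np.argmax(omega[:, order], axis=1)]


def segment_calls(calls: np.ndarray,
                  positions: np.ndarray | None = None) -> list[CallSegment]:
    """Collapse per-SNP calls (ordered by position) into maximal
    constant-copy-number segments."""
    calls = np.asarray(calls)
    if calls.ndim != 1 or len(calls) == 0:
        raise ValueError("need a non-empty 1-D call vector")
    if positions is not None and len(positions) != len(calls):
        raise ValueError("positions and calls length mismatch")
    boundaries = np.flatnonzero(np.diff(calls)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(calls)]))
    return [
        CallSegment(
            start=int(s), end=int(e), cn_label=int(calls[s]), n_snps=int(e - s),
            start_pos=None if positions is None else int(positions[s]),
            end_pos=None if positions is None else int(positions[e - 1]),
        )
        for s, e in zip(starts, ends)
    ]


def expand_segments(segments: Sequence[CallSegment]) -> np.ndarray:
    """Inverse of :func:`segment_calls` on the SNP-index scale."""
    return np.concatenate([np.full(seg.n_snps, seg.cn_label) for seg in segments])
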