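"""Simulation scenarios and error-rate metrics.

Two fixed copy-number segment patterns (245 SNPs each) are combined with a
grid of noise levels and contamination fractions; per-SNP log2-ratios are
drawn independently around the contamination-shrunk theoretical means.
Performance is summarized by three segment-level error rates:

    MC = P(call != j | true CN = j), j != 2   (misclassification)
    FN = P(call  = 2 | true CN != 2)          (aberration called normal)
    FP = P(call != 2 | true CN  = 2)          (normal called aberrant)

The scenario signal-to-noise ratio is defined as the CN=3 theoretical mean
(at the scenario's contamination) divided by the per-SNP noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import LogRatioTrack
from .signal_model import DEFAULT_BACKGROUND, ContaminationModel, theoretical_mean

__all__ = [
    "PATTERN_A",
    "PATTERN_B",
    "ScenarioSpec",
    "pattern",
    "scenario_grid",
    "simulate",
    "truth_vector",
    "aberrant_segments",
    "normal_segments",
    "mc_rate",
    "fn_rate",
    "fp_rate",
    "replicate_seed",
    "run_scenario",
    "rate_report",
]

#: Segment pattern of scenarios 1-4: (copy number, number of SNPs).
PATTERN_A: tuple[tuple[int, int], ...] = (
    (2, 10), (3, 5), (2, 50), (1, 10), (2, 50), (3, 20), (2, 50), (3, 40), (2, 10),
)

#: Segment pattern of scenarios 5-8, with a homozygous deletion and a CN=4 gain.
PATTERN_B: tuple[tuple[int, int], ...] = (
    (2, 10), (4, 5), (2, 50), (3, 10), (2, 50), (0, 20), (2, 50), (3, 40), (2, 10),
)

#: (SD, contamination fraction) of the four scenario columns, shared by both
#: patterns; SNR labels 7.3, 2.4, 1.8, 1.5 follow with b = 1.47.
SCENARIO_NOISE: tuple[tuple[float, float], ...] = (
    (0.05, 0.0), (0.15, 0.0), (0.2, 0.0), (0.2, 0.2),
)


def pattern(pattern_id: str) -> tuple[tuple[int, int], ...]:
    """The ordered (copy number, width) segment list of pattern "A" or "B"."""
    try:
        return {"A": PATTERN_A, "B": PATTERN_B}[pattern_id]
    except KeyError:
        raise ValueError(f"unknown pattern {pattern_id!r}; expected 'A' or 'B'")


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation condition: a true segment pattern plus noise SD,
    contamination fraction p and background factor b."""

    segments: tuple[tuple[int, int], ...]
    sd: float
    p: float = 0.0
    b: float = DEFAULT_BACKGROUND
    name: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("noise SD must be positive")

    @property
    def n_snps(self) -> int:
        return sum(w for _, w in self.segments)

    @property
    def snr(self) -> float:
        """CN=3 mean over noise SD, the scenario's signal-to-noise label."""
        return theoretical_mean(3, ContaminationModel(self.p, self.b)) / self.sd


def scenario_grid() -> list[ScenarioSpec]:
    """The eight published scenarios: patterns A (1-4) and B (5-8) crossed
    with the four (SD, contamination) conditions."""
    specs = []
    for pat_idx, pat in enumerate((PATTERN_A, PATTERN_B)):
        for cond_idx, (sd, p) in enumerate(SCENARIO_NOISE):
            specs.append(ScenarioSpec(segments=pat, sd=sd, p=p,
                                      name=str(pat_idx * 4 + cond_idx + 1)))
    return specs


def truth_vector(segments: Sequence[tuple[int, int]]) -> np.ndarray:
    return np.concatenate([np.full(w, cn, dtype=np.int64) for cn, w in segments])


def aberrant_segments(segments: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """(copy number, start, end) half-open SNP ranges of the non-diploid
    segments, in pattern order."""
    out = []
    start = 0
    for cn, w in segments:
        if cn != 2:
            out.append((cn, start, start + w))
        start += w
    return out


def normal_segments(segments: Sequence[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """(width, start, end) ranges of the truly diploid segments."""
    out = []
    start = 0
    for cn, w in segments:
        if cn == 2:
            out.append((w, start, start + w))
        start += w
    return out


def simulate(spec: ScenarioSpec, seed, *, chrom: str = "sim",
             spacing: int = 1000) -> tuple[LogRatioTrack, np.ndarray]:
    """Draw one replicate track: y_i ~ N(m(cn_i; p, b), sd^2) independently,
    with synthetic equally spaced positions.  Returns (track, truth)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = truth_vector(spec.segments)
    model = ContaminationModel(spec.p, spec.b)
    means = np.array([theoretical_mean(int(cn), model) for cn in truth])
    y = means + spec.sd * rng.standard_normal(len(truth))
    n = len(truth)
    track = LogRatioTrack(
        chrom=chrom,
        positions=np.arange(1, n + 1, dtype=np.int64) * spacing,
        snp_ids=np.array([f"snp{i + 1}" for i in range(n)]),
        y=y,
    )
    return track, truth


def _as_replicates(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    return calls[None, :] if calls.ndim == 1 else calls


def mc_rate(calls: np.ndarray, truth: np.ndarray,
            segment: tuple[int, int]) -> float:
    """Fraction of SNPs in an aberrant segment called anything but their
    true copy number, pooled over replicate rows of ``calls``."""
    start, end = segment
    seg_truth = np.asarray(truth)[start:end]
    if np.any(seg_truth == 2):
        raise ValueError("MC rate is undefined on diploid segments (that is FP)")
    return float(np.mean(_as_replicates(calls)[:, start:end] != seg_truth))


def fn_rate(calls: np.ndarray, truth: np.ndarray,
            segment: tuple[int, int]) -> float:
    """Fraction of SNPs in an aberrant segment called diploid."""
    start, end = segment
    seg_truth = np.asarray(truth)[start:end]
    if np.any(seg_truth == 2):
        raise ValueError("FN rate is undefined on diploid segments")
    return float(np.mean(_as_replicates(calls)[:, start:end] == 2))


def fp_rate(calls: np.ndarray, truth: np.ndarray,
            segments: Sequence[tuple[int, int]] | None = None) -> float:
    """Fraction of truly diploid SNPs called aberrant.

    ``segments`` restricts to specific (start, end) diploid ranges (for the
    by-segment-width breakdown); replicates are pooled, and pooling across
    patterns is simply concatenating their replicate call rows.
    """
    calls = _as_replicates(calls)
    truth = np.asarray(truth)
    if segments is None:
        mask = truth == 2
    else:
        mask = np.zeros(len(truth), dtype=bool)
        for start, end in segments:
            if np.any(truth[start:end] != 2):
                raise ValueError("FP segments must be truly diploid")
            mask[start:end] = True
    return float(np.mean(calls[:, mask] != 2))


def replicate_seed(base_seed: int, *path: int) -> int:
    """Stable derived seed below 2**31 from one base seed and an index
    path (scenario, replicate, stream, ...)."""
    ss = np.random.SeedSequence([int(base_seed), *(int(p) for p in path)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_scenario(spec: ScenarioSpec, n_reps: int, cfg=None, *,
                 n_burnin: int = 5000, n_samples: int = 5000,
                 base_seed: int = 0, scenario_index: int = 0,
                 progress=None) -> tuple[np.ndarray, np.ndarray]:
    """Run independent sampler replicates of one scenario.

    Each replicate simulates a fresh track and runs its own chain; returns
    the stacked per-replicate call matrix and the (shared) truth vector.
    """
    from .rjmcmc import run_chain

    truth = truth_vector(spec.segments)
    calls = np.empty((n_reps, spec.n_snps), dtype=np.int64)
    for r in range(n_reps):
        track, _ = simulate(spec, replicate_seed(base_seed, scenario_index, r, 0))
        res = run_chain(track, cfg, n_burnin, n_samples,
                        seed=replicate_seed(base_seed, scenario_index, r, 1))
        calls[r] = res.calls
        if progress is not None:
            progress(spec, r)
    return calls, truth


def rate_report(calls_by_scenario: dict[str, np.ndarray]) -> dict[str, "pd.DataFrame"]:
    """Summarize replicate calls as the three error-rate tables.

    ``mc_fn``: per aberrant segment and scenario, the MC and FN rates.
    ``fp``: per diploid segment width and noise condition, the FP rate
    pooled over both patterns' replicates (matching scenario pairs 1/5,
    2/6, 3/7, 4/8).
    """
    import pandas as pd

    specs = {s.name: s for s in scenario_grid()}
    recs = []
    for name, calls in sorted(calls_by_scenario.items(), key=lambda kv: int(kv[0])):
        spec = specs[name]
        truth = truth_vector(spec.segments)
        for cn, s, e in aberrant_segments(spec.segments):
            recs.append({
                "scenario": name, "sd": spec.sd, "p": spec.p,
                "snr": round(spec.snr, 1), "cn": cn, "n_snps": e - s,
                "mc": mc_rate(calls, truth, (s, e)),
                "fn": fn_rate(calls, truth, (s, e)),
            })
    fp_recs = []
    for cond, (sd, p) in enumerate(SCENARIO_NOISE):
        pair = [str(cond + 1), str(cond + 5)]
        present = [n for n in pair if n in calls_by_scenario]
        if not present:
            continue
        for width in (10, 50):
            num = 0
            den = 0
            for name in present:
                spec = specs[name]
                truth = truth_vector(spec.segments)
                segs = [(s, e) for w, s, e in normal_segments(spec.segments)
                        if w == width]
                sub = _as_replicates(calls_by_scenario[name])
                for s, e in segs:
                    num += int(np.sum(sub[:, s:e] != 2))
                    den += sub[:, s:e].size
            fp_recs.append({
                "scenarios": "/".join(present), "sd": sd, "p": p,
                "n_snps": width, "fp": num / den if den else float("nan"),
            })
    return {"mc_fn": pd.DataFrame(recs), "fp": pd.DataFrame(fp_recs)}
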