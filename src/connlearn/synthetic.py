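"""Synthetic ROI time-series cohorts with controlled modular correlation.

The generator emulates the product of a standard BOLD preprocessing chain:
band-limited (0.008-0.09 Hz at TR 2 s), zero-mean ROI signals whose joint
distribution is a stationary multivariate Gaussian with block (modular)
correlation structure.  A "deterministic" (learning) cohort increases
between-module coupling and merges modules from run 1 to run 2; a "null"
cohort keeps run 2 identical in distribution to run 1.  This provides a
ground-truthed stand-in for task fMRI cohorts so that every downstream stage
(connectome estimation, network statistics, Compression Flow, modularity,
group contrasts, edge filtering) is testable end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .connectome import Connectome

__all__ = [
    "CohortSpec",
    "ROITimeSeries",
    "module_labels",
    "target_correlation_matrix",
    "generate_cohort",
    "bandpass",
    "toy_graph",
    "edge_effect_cohort",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the learning-task regime: 15 subjects, 106 ROIs, 150
    scans per run at TR 2.0 s (about five minutes of acquisition), eight
    modules in run 1 collapsing to five in run 2, with between-module
    correlation rising from 0.05 to 0.15 while within-module correlation
    stays at 0.4.
    """

    n_subjects: int = 15
    n_rois: int = 106
    n_scans: int = 150
    tr_seconds: float = 2.0
    n_modules_run1: int = 8
    n_modules_run2: int = 5
    rho_within: float = 0.4
    rho_between_run1: float = 0.05
    rho_between_run2: float = 0.15
    condition: str = "deterministic"
    bandpass_hz: Tuple[float, float] = (0.008, 0.09)
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("deterministic", "null"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.n_scans <= 3:
            raise ValueError("n_scans must exceed 3")
        if not (self.n_modules_run1 <= self.n_rois and self.n_modules_run2 <= self.n_rois):
            raise ValueError("more modules than ROIs")
        for rho_between in (self.rho_between_run1, self.rho_between_run2):
            if not (0 <= rho_between <= self.rho_within < 1):
                raise ValueError(
                    "need 0 <= rho_between <= rho_within < 1, got "
                    f"between={rho_between}, within={self.rho_within}"
                )
        low, high = self.bandpass_hz
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0 <= low < high < nyquist):
            raise ValueError(f"band {self.bandpass_hz} outside (0, Nyquist={nyquist}) range")


@dataclass
class ROITimeSeries:
    """One subject/run's T x n ROI signal matrix, columns centered to zero mean."""

    subject_id: str
    run: int
    condition: str
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x n matrix")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def module_labels(spec: CohortSpec, run: int) -> np.ndarray:
    """Module assignment of each ROI for the given run.

    Run 1 splits the ROIs into ``n_modules_run1`` contiguous, near-equal
    blocks.  In the deterministic condition run 2 merges those blocks down to
    ``n_modules_run2`` groups (label taken modulo the run-2 count), modelling
    the integrative collapse of modules with learning; in the null condition
    run 2 keeps the run-1 assignment.
    """
    if run not in (1, 2):
        raise ValueError("run must be 1 or 2")
    base = (np.arange(spec.n_rois) * spec.n_modules_run1) // spec.n_rois
    if run == 1 or spec.condition == "null":
        return base
    return base % spec.n_modules_run2


def target_correlation_matrix(spec: CohortSpec, run: int) -> np.ndarray:
    """Block-constant target correlation matrix for one run.

    Entries are ``rho_within`` inside module blocks and the run's
    ``rho_between`` elsewhere, with unit diagonal.  The matrix is repaired to
    the nearest valid correlation matrix (eigenvalue clipping followed by
    re-normalisation to unit diagonal) if the requested combination is
    indefinite.
    """
    labels = module_labels(spec, run)
    rho_between = spec.rho_between_run1 if (run == 1 or spec.condition == "null") else spec.rho_between_run2
    same = labels[:, None] == labels[None, :]
    corr = np.where(same, spec.rho_within, rho_between)
    np.fill_diagonal(corr, 1.0)
    return _nearest_correlation(corr)


def _nearest_correlation(corr: np.ndarray, min_eig: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= min_eig:
        return corr
    clipped = (vecs * np.clip(vals, min_eig, None)) @ vecs.T
    d = np.sqrt(np.diag(clipped))
    if np.any(d <= 0):
        raise ValueError("correlation combination is not repairable")
    repaired = clipped / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def bandpass(series: np.ndarray, low_hz: float, high_hz: float, tr_seconds: float) -> np.ndarray:
    """Ideal (FFT brick-wall) band-pass filter applied per column.

    Frequency bins outside ``[low_hz, high_hz]`` are zeroed and the output is
    re-centered per column.  The band must lie below the Nyquist frequency
    ``1/(2 * tr_seconds)``.
    """
    series = np.asarray(series, dtype=float)
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz < nyquist):
        raise ValueError(f"band [{low_hz}, {high_hz}] outside [0, Nyquist={nyquist})")
    T = series.shape[0]
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    if low_hz == 0:  # the pass band never includes DC
        mask[0] = False
    spectrum = np.fft.rfft(series, axis=0)
    spectrum[~mask] = 0.0
    out = np.fft.irfft(spectrum, n=T, axis=0)
    return out - out.mean(axis=0, keepdims=True)


def generate_cohort(spec: CohortSpec) -> List[ROITimeSeries]:
    """Draw the full cohort: ``n_subjects`` subjects x 2 runs.

    Each series is sampled from a zero-mean multivariate normal with the
    run's target correlation matrix, band-pass filtered, and re-centered.
    Reproducible: the same spec (including seed) yields bitwise-identical
    cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    factors = {}
    for run in (1, 2):
        corr = target_correlation_matrix(spec, run)
        vals, vecs = np.linalg.eigh(corr)
        factors[run] = vecs * np.sqrt(np.clip(vals, 0, None))
    cohort = []
    for s in range(spec.n_subjects):
        subject_id = f"sub-{s + 1:02d}"
        for run in (1, 2):
            white = rng.standard_normal((spec.n_scans, spec.n_rois))
            data = white @ factors[run].T
            data = bandpass(data, *spec.bandpass_hz, tr_seconds=spec.tr_seconds)
            data -= data.mean(axis=0, keepdims=True)
            cohort.append(
                ROITimeSeries(subject_id=subject_id, run=run, condition=spec.condition, data=data)
            )
    return cohort


def toy_graph(kind: str, n: int = 5, weight: float = 1.0, seed: int = 0) -> Connectome:
    """Small named weighted graphs used as analysis fixtures.

    Kinds: ``star`` (node 0 is the hub), ``path``, ``complete``, ``triangle``
    (n fixed at 3), and ``planted_partition`` (four equal blocks, dense strong
    within-block weights and weak between-block weights).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    W = np.zeros((n, n))
    if kind == "star":
        W[0, 1:] = W[1:, 0] = weight
    elif kind == "path":
        idx = np.arange(n - 1)
        W[idx, idx + 1] = W[idx + 1, idx] = weight
    elif kind == "complete":
        W[:] = weight
        np.fill_diagonal(W, 0.0)
    elif kind == "triangle":
        n = 3
        W = np.full((3, 3), weight)
        np.fill_diagonal(W, 0.0)
    elif kind == "planted_partition":
        labels = (np.arange(n) * 4) // n
        same = labels[:, None] == labels[None, :]
        W = np.where(same, weight, 0.05 * weight)
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(0.9, 1.1, size=(n, n))
        W = W * np.triu(jitter, 1)
        W = W + W.T
        np.fill_diagonal(W, 0.0)
    else:
        raise ValueError(f"unknown toy graph kind {kind!r}")
    return Connectome(weights=W, meta={"kind": kind})


def edge_effect_cohort(
    n_subjects: int = 15,
    n_rois: int = 13,
    n_pos: int = 4,
    n_neg: int = 3,
    effect_sd: float = 1.5,
    noise_sd: float = 0.15,
    base_weight: float = 0.4,
    seed: int = 0,
) -> tuple:
    """Connectome cohort with planted between-run edge effects.

    Both runs share a common weight template plus independent per-subject
    Gaussian noise of ``noise_sd`` per edge; run 2 additionally shifts
    ``n_pos`` randomly chosen edges up and ``n_neg`` edges down by
    ``effect_sd * noise_sd``.  Returns ``(run1, run2, pos_edges, neg_edges)``
    where the runs are lists of :class:`Connectome` and the edge lists are
    upper-triangle ``(i, j)`` pairs.
    """
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n_rois, k=1)
    m = len(iu[0])
    if n_pos + n_neg > m:
        raise ValueError("more planted edges than edges available")
    template = np.abs(rng.normal(base_weight, 0.1, size=m))
    chosen = rng.choice(m, size=n_pos + n_neg, replace=False)
    pos_idx, neg_idx = chosen[:n_pos], chosen[n_pos:]

    def _materialize(run: int):
        conns = []
        for s in range(n_subjects):
            w = template + rng.normal(0.0, noise_sd, size=m)
            if run == 2:
                w[pos_idx] += effect_sd * noise_sd
                w[neg_idx] -= effect_sd * noise_sd
            W = np.zeros((n_rois, n_rois))
            W[iu] = w
            W = W + W.T
            conns.append(
                Connectome(weights=W, meta={"subject_id": f"sub-{s + 1:02d}", "run": run})
            )
        return conns

    run1, run2 = _materialize(1), _materialize(2)
    pos_edges = [(int(iu[0][k]), int(iu[1][k])) for k in pos_idx]
    neg_edges = [(int(iu[0][k]), int(iu[1][k])) for k in neg_idx]
    return run1, run2, pos_edges, neg_edges


def write_cohort(cohort: Sequence[ROITimeSeries], directory, spec: Optional[CohortSpec] = None) -> None:
    """Write one delimited-text matrix per subject/run plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for ts in cohort:
        fname = f"{ts.subject_id}_run-{ts.run}.tsv"
        np.savetxt(directory / fname, ts.data, delimiter="\t")
        records.append(
            {"subject_id": ts.subject_id, "run": ts.run, "condition": ts.condition, "file": fname}
        )
    manifest = {"series": records}
    if spec is not None:
        manifest["spec"] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_cohort(directory) -> List[ROITimeSeries]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cohort = []
    for rec in manifest["series"]:
        data = np.loadtxt(directory / rec["file"], delimiter="\t")
        cohort.append(
            ROITimeSeries(
                subject_id=rec["subject_id"],
                run=int(rec["run"]),
                condition=rec["condition"],
                data=data,
            )
        )
    return cohort
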