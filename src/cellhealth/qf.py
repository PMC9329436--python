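"""Quadratic-form (QF) distance feature reduction.

Each of the 12 detection parameters is summarised per well as an empirical
histogram (arcsinh-transformed for fluorescence, linear for scatter) on bin
edges shared with the plate's pooled negative controls.  The QF distance

    d_QF(h, g) = sqrt((h − g)ᵀ A (h − g))

between a test-well histogram and the pooled negative-control histogram,
with A a bin-similarity kernel, quantifies compound-induced change; unlike
a plain Euclidean distance it tolerates near-bin shifts.  Computed across
the 10-step dilution series this yields a dose-response curve of QF
distances per channel, which is reduced to two features — the point of
maximum rate of change (log10 µM) and the response range — giving the
24-value phenotype vector used for classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .errors import IncompatibleHistogramError, IncompleteSeriesError, SchemaError
from .flow import DEFAULT_PANEL, ChannelPanel, EventMatrix, qc_well

DEFAULT_N_BINS = 64
DEFAULT_COFACTOR = 150.0
DEFAULT_BANDWIDTH = 3.0  # kernel σ, in bins

MAX_RATE = "max_rate"
RANGE = "range"


@dataclass(frozen=True)
class Histogram:
    """Unit-mass histogram of transformed intensities for one channel."""

    bin_edges: np.ndarray
    mass: np.ndarray
    n_source_events: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))
        if len(self.mass) != len(self.bin_edges) - 1:
            raise ValueError("mass length must be len(bin_edges) - 1")
        if np.any(self.mass < 0):
            raise ValueError("histogram mass must be non-negative")
        if abs(self.mass.sum() - 1.0) >= 1e-9:
            raise ValueError("histogram mass must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.mass)


@dataclass(frozen=True)
class SimilarityKernel:
    """Symmetric PSD bin-similarity matrix with unit diagonal."""

    matrix: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        a = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("kernel matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0, atol=1e-12):
            raise ValueError("kernel matrix must have unit diagonal")
        if a.min() < -1e-12 or a.max() > 1 + 1e-12:
            raise ValueError("kernel entries must lie in [0, 1]")
        eigmin = float(np.linalg.eigvalsh(a)[0])
        if eigmin < -1e-8:
            raise ValueError(f"kernel is not positive semidefinite (λmin={eigmin:g})")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def gaussian_kernel(n_bins: int, bandwidth: float = DEFAULT_BANDWIDTH) -> SimilarityKernel:
    """Gaussian bin similarity A_ij = exp(−(i−j)² / 2σ²); PSD for all σ > 0."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    idx = np.arange(n_bins)
    diff = idx[:, None] - idx[None, :]
    return SimilarityKernel(matrix=np.exp(-diff.astype(float) ** 2 / (2 * bandwidth**2)),
                            bandwidth=bandwidth)


def transform_intensities(x: np.ndarray, *, linear: bool,
                          cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """arcsinh(x / cofactor) for fluorescence; identity for scatter."""
    x = np.asarray(x, dtype=float)
    return x if linear else np.arcsinh(x / cofactor)


def _is_scatter(channel: str, panel: ChannelPanel) -> bool:
    return channel in panel.scatter_channels


def compute_shared_edges(control_wells: list[EventMatrix], channel: str,
                         n_bins: int = DEFAULT_N_BINS, *,
                         panel: ChannelPanel = DEFAULT_PANEL,
                         cofactor: float = DEFAULT_COFACTOR) -> np.ndarray:
    """Bin edges from the pooled negative-control range: the 1st–99th
    percentile span split into n_bins − 2 interior bins, plus one overflow
    bin at each end so test and control histograms share support."""
    if n_bins < 4:
        raise ValueError("need at least 4 bins (2 interior + 2 overflow)")
    pooled = np.concatenate([w.channel(channel) for w in control_wells])
    t = transform_intensities(pooled, linear=_is_scatter(channel, panel),
                              cofactor=cofactor)
    lo, hi = np.percentile(t, [1.0, 99.0])
    if hi <= lo:
        hi = lo + 1e-6
    inner = np.linspace(lo, hi, n_bins - 1)
    return np.concatenate(([-np.inf], inner, [np.inf]))


def transform_and_bin(events: EventMatrix, channel: str,
                      n_bins: int = DEFAULT_N_BINS,
                      edges: np.ndarray | None = None, *,
                      panel: ChannelPanel = DEFAULT_PANEL,
                      cofactor: float = DEFAULT_COFACTOR) -> Histogram:
    """Empirical unit-mass histogram of one channel's transformed intensities.

    When ``edges`` is omitted they are computed from this well alone (same
    percentile rule); pipeline code passes edges pooled from negative
    controls so all wells on a plate share support.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    x = events.channel(channel)
    t = transform_intensities(x, linear=_is_scatter(channel, panel),
                              cofactor=cofactor)
    if edges is None:
        edges = compute_shared_edges([events], channel, n_bins, panel=panel,
                                     cofactor=cofactor)
    edges = np.asarray(edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1).astype(float)
    return Histogram(bin_edges=edges, mass=counts / counts.sum(),
                     n_source_events=len(t))


def qf_distance(h: Histogram, g: Histogram, kernel: SimilarityKernel) -> float:
    """sqrt((h−g)ᵀ A (h−g)); zero iff h == g when A is strictly PD."""
    if h.n_bins != g.n_bins or not np.allclose(
            h.bin_edges, g.bin_edges, rtol=1e-12, atol=0, equal_nan=False):
        raise IncompatibleHistogramError("histograms do not share bin edges")
    if kernel.n_bins != h.n_bins:
        raise IncompatibleHistogramError(
            f"kernel is {kernel.n_bins}×{kernel.n_bins} but histograms have "
            f"{h.n_bins} bins")
    d = h.mass - g.mass
    val = float(d @ kernel.matrix @ d)
    return float(np.sqrt(max(val, 0.0)))


@dataclass(frozen=True)
class QFCurve:
    """Replicate-averaged QF distance to negative control vs concentration."""

    compound_id: str
    channel: str
    concentrations: tuple[float, ...]  # ascending, µM
    distances: tuple[float, ...]
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.distances):
            raise ValueError("concentrations and distances must align")
        if any(b <= a for a, b in zip(self.concentrations, self.concentrations[1:])):
            raise ValueError("concentrations must be strictly ascending")
        if any(d < 0 for d in self.distances):
            raise ValueError("QF distances are non-negative")


def qf_dose_curve(test_wells: dict[float, list[EventMatrix]],
                  neg_controls: list[EventMatrix],
                  channel: str, kernel: SimilarityKernel, *,
                  compound_id: str = "",
                  panel: ChannelPanel = DEFAULT_PANEL,
                  cofactor: float = DEFAULT_COFACTOR,
                  qc_min_events: int = 1) -> QFCurve:
    """Dose-response curve of QF distances against the pooled negative control.

    ``test_wells`` maps concentration (µM) → replicate event matrices.
    Replicate distances are averaged (not event-pooled) so well-level
    variance stays visible; a concentration with one surviving replicate is
    used but flagged, one with none raises :class:`IncompleteSeriesError`.
    """
    controls = [w for w in neg_controls if qc_well(w, qc_min_events)]
    if not controls:
        raise IncompleteSeriesError("no negative-control well passes QC")
    n_bins = kernel.n_bins
    edges = compute_shared_edges(controls, channel, n_bins, panel=panel,
                                 cofactor=cofactor)
    pooled = EventMatrix(
        well="pooled-neg", channels=controls[0].channels,
        values=np.concatenate([w.values for w in controls]))
    g = transform_and_bin(pooled, channel, n_bins, edges, panel=panel,
                          cofactor=cofactor)

    concs = sorted(test_wells)
    distances, flags = [], []
    for c in concs:
        reps = [w for w in test_wells[c] if qc_well(w, qc_min_events)]
        if not reps:
            raise IncompleteSeriesError(
                f"{compound_id or 'compound'}: no usable replicate at {c:g} µM")
        if len(reps) < len(test_wells[c]) or len(reps) == 1:
            flags.append(f"{c:g} µM: {len(reps)} replicate(s) used")
        ds = [qf_distance(transform_and_bin(w, channel, n_bins, edges,
                                            panel=panel, cofactor=cofactor),
                          g, kernel) for w in reps]
        distances.append(float(np.mean(ds)))
    return QFCurve(compound_id=compound_id, channel=channel,
                   concentrations=tuple(concs), distances=tuple(distances),
                   flags=tuple(flags))


def control_noise_floor(neg_controls: list[EventMatrix], channel: str,
                        kernel: SimilarityKernel, *,
                        n_resamples: int = 50,
                        quantile: float = 0.95,
                        panel: ChannelPanel = DEFAULT_PANEL,
                        cofactor: float = DEFAULT_COFACTOR,
                        rng: np.random.Generator | None = None) -> float:
    """Null-detection threshold: the given quantile of QF distances between
    random half-splits of the pooled negative-control events."""
    rng = rng or np.random.default_rng(0)
    edges = compute_shared_edges(neg_controls, channel, kernel.n_bins,
                                 panel=panel, cofactor=cofactor)
    pooled = np.concatenate([w.values for w in neg_controls])
    channels = neg_controls[0].channels
    dists = []
    for _ in range(n_resamples):
        perm = rng.permutation(len(pooled))
        half = len(pooled) // 2
        a = EventMatrix(well="a", channels=channels, values=pooled[perm[:half]])
        b = EventMatrix(well="b", channels=channels, values=pooled[perm[half:]])
        ha = transform_and_bin(a, channel, kernel.n_bins, edges, panel=panel,
                               cofactor=cofactor)
        hb = transform_and_bin(b, channel, kernel.n_bins, edges, panel=panel,
                               cofactor=cofactor)
        dists.append(qf_distance(ha, hb, kernel))
    return float(np.quantile(dists, quantile))


def reduce_curve(curve: QFCurve) -> tuple[float, float]:
    """Reduce a QF dose-response curve to its two phenotype features.

    The curve is smoothed by isotonic regression on log10(concentration)
    (stress responses are assumed monotone in dose).  The max-rate point is
    the midpoint of the adjacent-concentration interval with the largest
    increase of the smoothed curve (ties break to the lowest interval); the
    response range is max − min of the smoothed curve.  Flat curves are
    legal and give range 0.
    """
    x = np.log10(np.asarray(curve.concentrations, dtype=float))
    y = np.asarray(curve.distances, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("QF distances must be finite")
    smoothed = IsotonicRegression(increasing=True).fit(x, y).predict(x)
    if len(x) < 2:
        return float(x[0]), 0.0
    jumps = np.diff(smoothed)
    j = int(np.argmax(jumps))  # first maximum → lowest interval on ties
    max_rate_point = float((x[j] + x[j + 1]) / 2.0)
    response_range = float(smoothed[-1] - smoothed[0])
    return max_rate_point, response_range


@dataclass(frozen=True)
class PhenotypeVector:
    """24-feature compound phenotype: (max-rate point, range) × 12 channels."""

    compound_id: str
    features: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features",
                           np.asarray(self.features, dtype=float))
        if len(self.features) != len(self.feature_names):
            raise ValueError("features and names must align")

    def value(self, name: str) -> float:
        return float(self.features[self.feature_names.index(name)])


def feature_names(panel: ChannelPanel = DEFAULT_PANEL) -> tuple[str, ...]:
    names = []
    for ch in panel.names:
        names.append(f"{ch}:{MAX_RATE}")
        names.append(f"{ch}:{RANGE}")
    return tuple(names)


def channel_feature_names(channels: list[str]) -> tuple[str, ...]:
    out = []
    for ch in channels:
        out.append(f"{ch}:{MAX_RATE}")
        out.append(f"{ch}:{RANGE}")
    return tuple(out)


def phenotype_vector(curves: list[QFCurve],
                     panel: ChannelPanel = DEFAULT_PANEL) -> PhenotypeVector:
    """Assemble the 24-feature phenotype from one QF curve per channel,
    in canonical channel order regardless of input order."""
    by_channel = {}
    for c in curves:
        if c.channel in by_channel:
            raise SchemaError(f"duplicate curve for channel {c.channel!r}")
        by_channel[c.channel] = c
    missing = [ch for ch in panel.names if ch not in by_channel]
    extra = [ch for ch in by_channel if ch not in panel.names]
    if missing or extra:
        raise SchemaError(
            f"need exactly one curve per canonical channel; "
            f"missing={missing}, unexpected={extra}")
    compound = curves[0].compound_id
    feats = []
    for ch in panel.names:
        mrp, rng_ = reduce_curve(by_channel[ch])
        feats.extend([mrp, rng_])
    return PhenotypeVector(compound_id=compound, features=np.array(feats),
                           feature_names=feature_names(panel))


# ---- screen-level convenience -----------------------------------------

def phenotypes_from_screen(platemap, wells: dict[str, EventMatrix],
                           kernel: SimilarityKernel | None = None, *,
                           panel: ChannelPanel = DEFAULT_PANEL,
                           cofactor: float = DEFAULT_COFACTOR,
                           qc_min_events: int = 1) -> list[PhenotypeVector]:
    """Run the full reduction for every compound on a plate.

    ``wells`` maps well address → :class:`EventMatrix` (one logical
    12-channel matrix per well).  Negative-control wells are pooled per
    plate.
    """
    from .plates import ROLE_NEGATIVE, ROLE_TEST  # local to avoid cycle

    kernel = kernel or gaussian_kernel(DEFAULT_N_BINS)
    negs = [wells[w] for w in platemap.wells_with_role(ROLE_NEGATIVE)
            if w in wells]
    out = []
    for compound in platemap.compounds:
        grouped: dict[float, list[EventMatrix]] = {}
        for addr in platemap.test_wells_for(compound):
            if addr not in wells:
                continue
            conc = platemap.wells[addr].concentration
            grouped.setdefault(conc, []).append(wells[addr])
        curves = [qf_dose_curve(grouped, negs, ch, kernel,
                                compound_id=compound, panel=panel,
                                cofactor=cofactor, qc_min_events=qc_min_events)
                  for ch in panel.names]
        out.append(phenotype_vector(curves, panel))
    return out


def phenotypes_to_frame(phenotypes: list[PhenotypeVector]) -> pd.DataFrame:
    rows = []
    for p in phenotypes:
        row = {"compound_id": p.compound_id}
        row.update(dict(zip(p.feature_names, p.features)))
        rows.append(row)
    return pd.DataFrame(rows)


def phenotypes_from_frame(frame: pd.DataFrame) -> list[PhenotypeVector]:
    feature_cols = [c for c in frame.columns if c != "compound_id"]
    return [PhenotypeVector(compound_id=str(r["compound_id"]),
                            features=np.array([r[c] for c in feature_cols]),
                            feature_names=tuple(feature_cols))
            for _, r in frame.iterrows()]
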