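"""Phase dynamics: from parcellated BOLD series to leading-eigenvector series.

The pipeline implemented here is the per-scan half of Leading Eigenvector
Dynamics Analysis (LEiDA):

1. demean/detrend each parcel time series and (optionally) band-pass it to
   the low-frequency BOLD band (0.01-0.08 Hz by default);
2. take the instantaneous phase of each parcel's analytic (Hilbert) signal;
3. at every volume build the instantaneous phase-coherence matrix
   ``C[n, p] = cos(theta_n - theta_p)``;
4. reduce each matrix to its leading eigenvector, a unit vector whose
   elements are (up to the eigenvector normalization) the cosine of each
   region's phase offset from the dominant phase direction.

``C`` is always of the form ``c c^T + s s^T`` with ``c = cos(theta)`` and
``s = sin(theta)``, hence positive semi-definite with rank at most 2 and
``lambda_1 + lambda_2 = N``.  The per-volume eigenproblem therefore reduces
to a 2x2 problem in the span of ``{c, s}``, which is how
:func:`eigenvector_series` computes it; the generic :func:`leading_eigenvector`
uses a dense symmetric solver and serves arbitrary symmetric input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal

from .exceptions import ConfigurationError, DegenerateSignalError, ValidationError

__all__ = [
    "ParcelTimeSeries",
    "LeadingEigenvectorSeries",
    "preprocess_series",
    "instantaneous_phase",
    "phase_coherence",
    "leading_eigenvector",
    "canonicalize_sign",
    "eigenvector_series",
]

#: Default analysis band in Hz (low-frequency BOLD fluctuations).
DEFAULT_BAND = (0.01, 0.08)

#: Order of the Butterworth band-pass prototype (applied forward-backward,
#: so the effective magnitude response is squared and the phase is zero).
FILTER_ORDER = 2

#: Relative eigenvalue-gap threshold below which the leading eigenvector is
#: considered ambiguous (degenerate top eigenspace).
EIG_TIE_RTOL = 1e-10


@dataclass
class ParcelTimeSeries:
    """One scan's parcellated BOLD signal.

    Parameters
    ----------
    data : ndarray of shape (T, N)
        BOLD amplitude (arbitrary units), one column per region.
    tr : float
        Repetition time in seconds (sampling interval).
    region_labels : list of str
        Region names, one per column (AAL-90 order for real data).
    scan_id : str
        Identifier used in manifests and output tables.
    """

    data: np.ndarray
    tr: float
    region_labels: list[str] = field(default_factory=list)
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError(f"scan {self.scan_id!r}: data must be 2-D (T x N)")
        if self.data.shape[0] < 3:
            raise ValidationError(f"scan {self.scan_id!r}: need at least 3 volumes")
        if not np.isfinite(self.data).all():
            raise ValidationError(f"scan {self.scan_id!r}: non-finite values in data")
        if self.tr <= 0:
            raise ValidationError(f"scan {self.scan_id!r}: TR must be positive")
        if not self.region_labels:
            self.region_labels = [f"R{i + 1:03d}" for i in range(self.data.shape[1])]
        if len(self.region_labels) != self.data.shape[1]:
            raise ValidationError(
                f"scan {self.scan_id!r}: {len(self.region_labels)} labels for "
                f"{self.data.shape[1]} columns"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass
class LeadingEigenvectorSeries:
    """Per-scan sequence of sign-canonicalized unit leading eigenvectors.

    ``vectors`` has one row per retained volume; ``volume_index`` maps each
    row back to the original volume index (edge volumes are dropped).
    """

    vectors: np.ndarray
    volume_index: np.ndarray
    scan_id: str = ""

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_regions(self) -> int:
        return self.vectors.shape[1]


def preprocess_series(
    ts: ParcelTimeSeries, band: tuple[float, float] | None = DEFAULT_BAND
) -> ParcelTimeSeries:
    """Demean, detrend and (optionally) band-pass every parcel series.

    Each column has its least-squares linear trend (including the mean)
    removed.  When ``band`` is given, a zero-phase Butterworth band-pass
    (order ``FILTER_ORDER``, applied forward-backward with ``sosfiltfilt``)
    restricts the signal to that band.  Pass ``band=None`` for inputs that
    are already band-limited.

    Parameters
    ----------
    ts : ParcelTimeSeries
    band : (low, high) in Hz, or None
        Must satisfy ``0 < low < high < Nyquist`` where Nyquist is
        ``1 / (2 TR)``.

    Returns
    -------
    ParcelTimeSeries
        A new series with the same TR, labels and scan id.
    """
    detrended = signal.detrend(ts.data, axis=0, type="linear")
    if band is None:
        out = detrended
    else:
        low, high = float(band[0]), float(band[1])
        nyquist = 0.5 / ts.tr
        if not (0.0 < low < high < nyquist):
            raise ConfigurationError(
                f"band {band} must satisfy 0 < low < high < Nyquist ({nyquist:g} Hz)"
            )
        sos = signal.butter(
            FILTER_ORDER, (low, high), btype="bandpass", fs=1.0 / ts.tr, output="sos"
        )
        padlen = 3 * (2 * sos.shape[0] + 1)
        if ts.n_volumes <= padlen:
            raise ConfigurationError(
                f"scan {ts.scan_id!r}: {ts.n_volumes} volumes are too few to "
                f"band-pass (need more than {padlen})"
            )
        out = signal.sosfiltfilt(sos, detrended, axis=0)
        # filtering reintroduces a tiny DC offset; remove it so downstream
        # Hilbert phases are well defined
        out = out - out.mean(axis=0)
    return ParcelTimeSeries(out, ts.tr, list(ts.region_labels), ts.scan_id)


def instantaneous_phase(ts: ParcelTimeSeries) -> np.ndarray:
    """Instantaneous Hilbert phase of every (zero-mean) parcel series.

    Returns
    -------
    ndarray of shape (T, N)
        ``theta[t, n]`` = argument of the analytic signal of column ``n`` at
        volume ``t``, in radians within ``(-pi, pi]``.

    Raises
    ------
    DegenerateSignalError
        If any column is identically zero (its phase is undefined).
    """
    amplitude = np.abs(ts.data).max(axis=0)
    dead = np.flatnonzero(amplitude == 0.0)
    if dead.size:
        names = ", ".join(ts.region_labels[i] for i in dead[:5])
        raise DegenerateSignalError(
            f"scan {ts.scan_id!r}: all-zero column(s) ({names}); phase undefined"
        )
    analytic = signal.hilbert(ts.data, axis=0)
    return np.angle(analytic)


def phase_coherence(theta_row: np.ndarray) -> np.ndarray:
    """Instantaneous phase-coherence matrix for one volume.

    ``C[n, p] = cos(theta_n - theta_p)``, computed as
    ``c c^T + s s^T`` with ``c = cos(theta)``, ``s = sin(theta)``.  The
    result is symmetric with unit diagonal, positive semi-definite and of
    rank at most 2.
    """
    theta_row = np.asarray(theta_row, dtype=float)
    if not np.isfinite(theta_row).all():
        raise ValidationError("phases must be finite")
    c = np.cos(theta_row)
    s = np.sin(theta_row)
    return np.outer(c, c) + np.outer(s, s)


def canonicalize_sign(v: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Resolve the sign ambiguity of an eigenvector deterministically.

    The vector is flipped so that the sum of its elements is positive (the
    fully phase-coherent pattern is then all-positive).  If the sum is zero
    within ``tol``, the flip makes the largest-magnitude element positive.
    The map is idempotent and satisfies ``canonicalize(-v) = canonicalize(v)``.
    """
    v = np.asarray(v, dtype=float)
    total = v.sum()
    if abs(total) >= tol:
        return v if total > 0 else -v
    pivot = np.argmax(np.abs(v))
    if v[pivot] < 0:
        return -v
    return v.copy()


def leading_eigenvector(C: np.ndarray) -> np.ndarray:
    """Unit-norm, sign-canonicalized eigenvector of the largest eigenvalue.

    Works for any symmetric matrix.  If the top two eigenvalues coincide
    within ``EIG_TIE_RTOL * N`` a warning is emitted and the solver's first
    vector is kept (after canonicalization), so the result is deterministic.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-10):
        raise ValidationError("coherence matrix must be square and symmetric")
    eigvals, eigvecs = linalg.eigh(C, subset_by_index=(n - 2, n - 1))
    if eigvals[1] - eigvals[0] < EIG_TIE_RTOL * n:
        warnings.warn(
            "leading eigenvalue is (near-)degenerate; eigenvector ambiguous",
            RuntimeWarning,
            stacklevel=2,
        )
    v = eigvecs[:, 1]
    v = v / np.linalg.norm(v)
    return canonicalize_sign(v)


def _leading_from_phases(theta: np.ndarray) -> np.ndarray:
    """Leading eigenvectors for all volumes at once via the rank-2 structure.

    For each row of ``theta`` the coherence matrix is ``c c^T + s s^T``, so
    its leading eigenvector lies in span{c, s} and solves the 2x2 Gram
    problem ``G w = lambda w`` with ``G = [[c.c, c.s], [c.s, s.s]]``.

    Returns the (T, N) matrix of unit-norm eigenvectors, NOT yet
    sign-canonicalized.
    """
    c = np.cos(theta)
    s = np.sin(theta)
    a = np.einsum("tn,tn->t", c, c)
    b = np.einsum("tn,tn->t", c, s)
    d = np.einsum("tn,tn->t", s, s)
    # closed-form top eigenpair of [[a, b], [b, d]]
    half_trace = 0.5 * (a + d)
    disc = np.sqrt(0.25 * (a - d) ** 2 + b**2)
    lam = half_trace + disc
    # eigenvector (w0, w1): use the numerically larger of the two algebraic
    # forms to avoid cancellation when b ~ 0
    w0_a, w1_a = b, lam - a
    w0_b, w1_b = lam - d, b
    use_b = np.hypot(w0_b, w1_b) > np.hypot(w0_a, w1_a)
    w0 = np.where(use_b, w0_b, w0_a)
    w1 = np.where(use_b, w1_b, w1_a)
    # degenerate case b = 0, a = d: both forms vanish; fall back to (1, 0)
    zero = (np.hypot(w0, w1) == 0.0)
    w0 = np.where(zero, 1.0, w0)
    w1 = np.where(zero, 0.0, w1)
    v = w0[:, None] * c + w1[:, None] * s
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    return v / norms


def _canonicalize_rows(vectors: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Vectorized sign canonicalization over rows."""
    sums = vectors.sum(axis=1)
    flip = sums < 0
    ties = np.abs(sums) < tol
    if ties.any():
        pivots = np.argmax(np.abs(vectors[ties]), axis=1)
        flip[ties] = vectors[ties, pivots] < 0
    out = vectors.copy()
    out[flip] *= -1.0
    return out


def eigenvector_series(
    ts: ParcelTimeSeries, band: tuple[float, float] | None = DEFAULT_BAND
) -> LeadingEigenvectorSeries:
    """Full per-scan LEiDA reduction: preprocess, phases, leading eigenvectors.

    The first and last volume are discarded to avoid Hilbert-transform
    boundary transients, so the output has ``T - 2`` rows.  Every row is a
    unit-norm, sign-canonicalized leading eigenvector of that volume's
    instantaneous phase-coherence matrix.
    """
    pre = preprocess_series(ts, band)
    theta = instantaneous_phase(pre)
    vectors = _leading_from_phases(theta)
    vectors = _canonicalize_rows(vectors)
    keep = np.arange(1, ts.n_volumes - 1)
    return LeadingEigenvectorSeries(
        vectors=vectors[keep], volume_index=keep, scan_id=ts.scan_id
    )
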