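"""Elliptic Fourier descriptors (EFD) of closed outlines.

A closed planar curve is represented by truncated Fourier series of its
coordinate functions x(t), y(t) over one period of the curvilinear abscissa:

    x(t) = a0 + sum_n [ a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T) ]
    y(t) = c0 + sum_n [ c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T) ]

Coefficients are computed with the classical closed-form per-segment
accumulation for a piecewise-linear (chord-length parameterized) polygon,
which is exact for polygons and does not require equally spaced points.
Normalization standardizes the descriptor against translation, in-plane
rotation, uniform scaling and the choice of starting point, using the
first-harmonic ellipse, so that normalized coefficients describe pure shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import Outline

__all__ = [
    "EFDescriptor",
    "HarmonicPowerProfile",
    "FeatureVector",
    "compute_efd",
    "normalize_efd",
    "harmonic_power",
    "to_feature_vector",
    "reconstruct_outline",
    "EllipticFourierFeaturizer",
]


@dataclass(frozen=True)
class EFDescriptor:
    """Elliptic Fourier coefficient set for one outline.

    Attributes
    ----------
    a0, c0 : float
        Centroid offset terms (units of the source outline). Zeroed after
        normalization.
    harmonics : ndarray of shape (n_harmonics, 4)
        Rows are per-harmonic quadruples ``(a_n, b_n, c_n, d_n)``.
    normalized : bool
        True once the descriptor has been standardized for position, scale,
        rotation and starting point.
    specimen_id : str
    """

    a0: float
    c0: float
    harmonics: np.ndarray
    normalized: bool = False
    specimen_id: str = ""

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def __post_init__(self):
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError("harmonics must be an (N, 4) array with N >= 1")
        object.__setattr__(self, "harmonics", h)


@dataclass(frozen=True)
class HarmonicPowerProfile:
    """Per-harmonic power and cumulative power fractions.

    ``power[n-1] = (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2`` and
    ``cumulative_fraction[k-1]`` is the power of harmonics 1..k divided by
    the total over the first ``n_reference`` harmonics.
    """

    power: np.ndarray
    cumulative_fraction: np.ndarray
    n_reference: int


@dataclass(frozen=True)
class FeatureVector:
    """Flattened normalized coefficients (a_1, b_1, c_1, d_1, ..., d_k)."""

    specimen_id: str
    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(c)):
            raise ValueError("feature vector contains non-finite values")
        object.__setattr__(self, "coefficients", c)


def _closed_diffs(points: np.ndarray):
    """Segment vectors and chord lengths of the closed polygon."""
    pts = np.asarray(points, dtype=float)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 0
    return d[keep], dt[keep], pts[0]


def compute_efd(outline: Outline, n_harmonics: int) -> EFDescriptor:
    """Elliptic Fourier transform of a closed outline.

    Uses the closed-form coefficient integrals for a chord-length
    parameterized polygon (piecewise-linear accumulation, not an FFT), so
    unequal point spacing is handled exactly.

    Parameters
    ----------
    outline : Outline
        Closed outline with at least 3 distinct points.
    n_harmonics : int
        Number of harmonics N >= 1 to retain.

    Returns
    -------
    EFDescriptor with ``normalized=False``.
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    d, dt, p0 = _closed_diffs(outline.points)
    if len(dt) < 3:
        raise ValueError(
            f"outline {outline.specimen_id!r} has fewer than 3 distinct points"
        )
    T = dt.sum()
    if T <= 0:
        raise ValueError(f"outline {outline.specimen_id!r} has zero perimeter")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    phi = (2.0 * np.pi / T) * t  # accumulated phase at segment endpoints

    n = np.arange(1, n_harmonics + 1)[:, None]
    cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
    sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
    coef = T / (2.0 * (n.ravel() ** 2) * np.pi**2)
    vx = d[:, 0] / dt
    vy = d[:, 1] / dt
    a = coef * (cos_d @ vx)
    b = coef * (sin_d @ vx)
    c = coef * (cos_d @ vy)
    dd = coef * (sin_d @ vy)

    # DC terms: integrate the piecewise-linear x(t), y(t) over one period
    xi = np.cumsum(d[:, 0]) - vx * t[1:]
    eta = np.cumsum(d[:, 1]) - vy * t[1:]
    dt2 = np.diff(t**2)
    a0 = p0[0] + (np.sum(vx / 2.0 * dt2) + np.sum(xi * dt)) / T
    c0 = p0[1] + (np.sum(vy / 2.0 * dt2) + np.sum(eta * dt)) / T

    return EFDescriptor(
        a0=float(a0),
        c0=float(c0),
        harmonics=np.column_stack([a, b, c, dd]),
        normalized=False,
        specimen_id=outline.specimen_id,
    )


def _shift_start(h: np.ndarray, theta: float) -> np.ndarray:
    """Rotate the starting point along the curve by parameter angle theta."""
    out = np.empty_like(h)
    for i in range(h.shape[0]):
        nth = (i + 1) * theta
        m = np.array(
            [[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]]
        )
        hm = h[i].reshape(2, 2) @ m
        out[i] = hm.ravel()
    return out


def _rotate_plane(h: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the shape in the plane by -psi (align major axis to x)."""
    r = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(h)
    for i in range(h.shape[0]):
        out[i] = (r @ h[i].reshape(2, 2)).ravel()
    return out


def _standardize(h: np.ndarray, theta: float) -> np.ndarray:
    """Full first-ellipse standardization for one start-point candidate."""
    hs = _shift_start(h, theta)
    a1, b1, c1, d1 = hs[0]
    psi = np.arctan2(c1, a1)
    hr = _rotate_plane(hs, psi)
    scale = np.hypot(*(hr[0].reshape(2, 2) @ np.array([1.0, 0.0])))
    hr /= scale
    if hr[0, 3] < 0:
        # clockwise traversal: reverse parameter direction (t -> -t)
        hr[:, 1] *= -1.0
        hr[:, 3] *= -1.0
    return hr


def _phase_candidates(h: np.ndarray) -> list[float]:
    """Candidate start-point shifts from the first-harmonic ellipse.

    The half-angle formula fixes the major-axis phase only up to pi; both
    representatives are returned. When the first-harmonic ellipse is nearly
    circular (axis ratio > 0.99) the phase is numerically unstable, so the
    second harmonic supplies the phase instead (determined modulo pi/2,
    giving four candidates). A deterministic lexicographic rule picks among
    candidates afterwards.
    """
    a1, b1, c1, d1 = h[0]
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    # choose the representative whose axis at t=0 is the major axis
    m = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    axes = h[0].reshape(2, 2) @ m
    if np.hypot(axes[0, 1], axes[1, 1]) > np.hypot(axes[0, 0], axes[1, 0]):
        theta += np.pi / 2.0
        m = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        axes = h[0].reshape(2, 2) @ m
    major = np.hypot(axes[0, 0], axes[1, 0])
    minor = np.hypot(axes[0, 1], axes[1, 1])
    cands = [theta, theta + np.pi]
    if major > 0 and minor / major > 0.99 and h.shape[0] >= 2:
        # Near-circular first harmonic: its phase confounds plane rotation
        # with start shift, so take the phase from the strongest higher
        # harmonic m. Decompose that harmonic into a circular component
        # p*R(gp) and an anti-circular component q*S*R(gq); under a start
        # shift tau (with the plane rotation slaved to harmonic 1) their
        # standardized phases advance by (m-1)tau and (m+1)tau, giving
        # finite, exactly pose-covariant candidate sets.
        hi = h[1:min(h.shape[0], 6)]
        power = np.sum(hi**2, axis=1)
        m = int(np.argmax(power)) + 2
        am, bm, cm, dm = h[m - 1]
        a1, b1, c1, d1 = h[0]
        phi1 = np.arctan2(c1 - b1, a1 + d1)  # circular phase of harmonic 1
        p = 0.5 * np.hypot(am + dm, cm - bm)
        q = 0.5 * np.hypot(am - dm, bm + cm)
        gp = np.arctan2(cm - bm, am + dm)
        gq = np.arctan2(-(bm + cm), am - dm)
        total = np.hypot(p, q)
        cands = []
        if total > 0 and p >= 0.05 * total:
            cands += [
                (phi1 - gp) / (m - 1) + 2 * np.pi * k / (m - 1)
                for k in range(m - 1)
            ]
        if total > 0 and q >= 0.05 * total:
            cands += [
                -(gq + phi1) / (m + 1) + 2 * np.pi * k / (m + 1)
                for k in range(m + 1)
            ]
        if not cands:  # essentially a circle: any phase is canonical
            cands = [theta, theta + np.pi]
    return cands


def normalize_efd(d: EFDescriptor) -> EFDescriptor:
    """Standardize a descriptor for position, scale, rotation and start point.

    The classical first-ellipse standardization: the starting point is moved
    to the tip of the first-harmonic semi-major axis, the shape is rotated so
    that axis lies along x, coefficients are divided by the semi-major axis
    magnitude, and the centroid terms are dropped. The residual two-fold
    (near-circular: four-fold) phase ambiguity is resolved by a deterministic
    lexicographic rule on the rounded coefficient vector, and traversal
    direction is canonicalized so the normalized d_1 is positive.

    After normalization ``a_1 = 1``, ``b_1 = c_1 = 0`` (to rounding) and the
    descriptor is invariant to the input's pose and starting point.
    """
    if d.normalized:
        raise ValueError("descriptor is already normalized")
    mag1 = np.hypot(d.harmonics[0, 0], d.harmonics[0, 2]) + np.hypot(
        d.harmonics[0, 1], d.harmonics[0, 3]
    )
    if mag1 <= 0:
        raise ValueError("first-harmonic ellipse is degenerate")
    best = None
    for theta in _phase_candidates(d.harmonics):
        cand = _standardize(d.harmonics, theta)
        key = tuple(np.round(cand.ravel(), 9))
        if best is None or key > best[0]:
            best = (key, cand)
    return EFDescriptor(
        a0=0.0,
        c0=0.0,
        harmonics=best[1],
        normalized=True,
        specimen_id=d.specimen_id,
    )


def harmonic_power(d: EFDescriptor, n_reference: int = 20) -> HarmonicPowerProfile:
    """Per-harmonic power P_n = (a_n^2+b_n^2+c_n^2+d_n^2)/2 and the cumulative
    fraction of the total over the first ``n_reference`` harmonics."""
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    if d.n_harmonics < n_reference:
        raise ValueError(
            f"descriptor has {d.n_harmonics} harmonics; {n_reference} required "
            "(recompute the descriptor with more harmonics)"
        )
    h = d.harmonics[:n_reference]
    power = 0.5 * np.sum(h**2, axis=1)
    total = power.sum()
    if total <= 0:
        raise ValueError("zero total harmonic power")
    return HarmonicPowerProfile(
        power=power,
        cumulative_fraction=np.cumsum(power) / total,
        n_reference=n_reference,
    )


def to_feature_vector(d: EFDescriptor, k_harmonics: int = 6) -> FeatureVector:
    """Flatten the first ``k_harmonics`` quadruples of a normalized descriptor
    into the 4k-dimensional feature vector used for classification."""
    if not d.normalized:
        raise ValueError("feature vectors are built from normalized descriptors")
    if k_harmonics < 1:
        raise ValueError("k_harmonics must be >= 1")
    if d.n_harmonics < k_harmonics:
        raise ValueError(
            f"descriptor has {d.n_harmonics} harmonics, need {k_harmonics}"
        )
    return FeatureVector(
        specimen_id=d.specimen_id,
        coefficients=d.harmonics[:k_harmonics].ravel().copy(),
    )


def reconstruct_outline(d: EFDescriptor, n_points: int) -> Outline:
    """Evaluate the truncated Fourier series at uniform parameter values."""
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, d.n_harmonics + 1)[:, None]
    ang = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(ang), np.sin(ang)
    h = d.harmonics
    x = d.a0 + h[:, 0] @ cos + h[:, 1] @ sin
    y = d.c0 + h[:, 2] @ cos + h[:, 3] @ sin
    return Outline(points=np.column_stack([x, y]), specimen_id=d.specimen_id)


class EllipticFourierFeaturizer:
    """Transformer mapping outlines to normalized EFD feature matrices.

    Parameters
    ----------
    k_harmonics : int, default 6
        Harmonics retained in the feature vector (4 coefficients each; the
        default yields the conventional 24-coefficient shape descriptor).
    n_points : int, default 360
        Equidistant points resampled along each outline before the transform.
    n_harmonics_computed : int, default 20
        Harmonics computed before truncation; also the reference total for
        harmonic-power diagnostics.

    The transformer is stateless (``fit`` is a no-op) and follows the
    scikit-learn transformer API, so it composes with sklearn pipelines.
    """

    def __init__(self, k_harmonics: int = 6, n_points: int = 360,
                 n_harmonics_computed: int = 20):
        self.k_harmonics = k_harmonics
        self.n_points = n_points
        self.n_harmonics_computed = n_harmonics_computed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "k_harmonics": self.k_harmonics,
            "n_points": self.n_points,
            "n_harmonics_computed": self.n_harmonics_computed,
        }

    def set_params(self, **params) -> "EllipticFourierFeaturizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "EllipticFourierFeaturizer":
        self.n_features_out_ = 4 * self.k_harmonics
        return self

    def describe(self, outline: Outline) -> EFDescriptor:
        """Normalized descriptor of one outline (resampled first)."""
        from .imaging import resample_outline

        o = resample_outline(outline, self.n_points)
        return normalize_efd(compute_efd(o, self.n_harmonics_computed))

    def transform(self, X) -> np.ndarray:
        """Map a sequence of Outline objects to an (n, 4k) feature matrix."""
        self.fit(X)
        rows = [
            to_feature_vector(self.describe(o), self.k_harmonics).coefficients
            for o in X
        ]
        return np.asarray(rows, dtype=float)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    @staticmethod
    def feature_names(k_harmonics: int = 6) -> list[str]:
        return [
            f"{letter}{n}"
            for n in range(1, k_harmonics + 1)
            for letter in "abcd"
        ]
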