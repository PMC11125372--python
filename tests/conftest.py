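"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from vitimorph.imaging import Outline


# ---------------------------------------------------------------------------
# independent quadrature oracle for elliptic Fourier coefficients
#
# Integrates the Fourier coefficient integrals of the piecewise-linear
# coordinate functions x(t), y(t) numerically on a dense uniform grid,
# without using any of the package's closed-form accumulation code.


def quadrature_efd(points: np.ndarray, n_harmonics: int, m: int = 100_000):
    """EFD coefficients by dense rectangle-rule quadrature of the integrals.

    Returns (a0, c0, harmonics) with harmonics of shape (n_harmonics, 4).
    """
    pts = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    T = s[-1]
    t = (np.arange(m) + 0.5) * (T / m)
    x = np.interp(t, s, pts[:, 0])
    y = np.interp(t, s, pts[:, 1])
    dt = T / m
    a0 = x.sum() * dt / T
    c0 = y.sum() * dt / T
    out = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        cos = np.cos(2 * np.pi * n * t / T)
        sin = np.sin(2 * np.pi * n * t / T)
        out[n - 1] = (
            2 / T * np.sum(x * cos) * dt,
            2 / T * np.sum(x * sin) * dt,
            2 / T * np.sum(y * cos) * dt,
            2 / T * np.sum(y * sin) * dt,
        )
    return a0, c0, out


def harmonic_powers(harmonics: np.ndarray) -> np.ndarray:
    return 0.5 * np.sum(np.asarray(harmonics) ** 2, axis=1)


# ---------------------------------------------------------------------------
# shape factories


def circle_outline(r=1.0, cx=0.0, cy=0.0, n=360, specimen_id="circle"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack([cx + r * np.cos(t), cy + r * np.sin(t)]),
        specimen_id,
    )


def ellipse_outline(a=2.0, b=1.0, n=720, specimen_id="ellipse"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Outline(
        np.column_stack([a * np.cos(t), b * np.sin(t)]), specimen_id
    )


def square_outline(side=1.0, specimen_id="square"):
    s = side
    return Outline(
        np.array([[0, 0], [s, 0], [s, s], [0, s]], dtype=float), specimen_id
    )


def star_outline(rng, n_lobes=None, n=480, specimen_id="star"):
    """Random smooth star-convex test shape (simple by construction)."""
    if n_lobes is None:
        n_lobes = int(rng.integers(2, 6))
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 1.0 + 0.25 * np.cos(n_lobes * t + rng.uniform(0, 2 * np.pi))
    r += 0.1 * np.cos((n_lobes + 1) * t + rng.uniform(0, 2 * np.pi))
    return Outline(
        np.column_stack([r * np.cos(t), r * np.sin(t)]), specimen_id
    )


def random_polygon(rng, n_vertices):
    """Random simple polygon: star-convex with jittered radii."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    if np.min(np.diff(ang)) < 1e-3:
        ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = rng.uniform(0.5, 1.5, n_vertices)
    return Outline(
        np.column_stack([r * np.cos(ang), r * np.sin(ang)]), "poly"
    )


def posed(outline: Outline, rng) -> Outline:
    """Random translation, rotation, scaling and start-point shift."""
    pts = outline.points
    ang = rng.uniform(0, 2 * np.pi)
    R = np.array(
        [[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]]
    )
    scale = rng.uniform(0.2, 5.0)
    shift = rng.uniform(-20, 20, 2)
    k = int(rng.integers(0, len(pts)))
    return Outline(np.roll(pts, k, axis=0) @ R.T * scale + shift,
                   outline.specimen_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Session-scoped rasterized cohort: 5 reference classes + unknowns.

    Unknowns are drawn from the sylvestris-like template with mild fossil
    distortion, mirroring the intended use (modern references, fossil
    unknowns).
    """
    import pandas as pd
    from vitimorph.synthetic import (
        EURASIAN5,
        SYLVESTRIS_TEMPLATE,
        SyntheticCohortSpec,
        make_default_templates,
        sample_cohort,
        sample_outline,
        rasterize_outline,
    )
    from vitimorph.synthetic import _write_png

    root = tmp_path_factory.mktemp("cohort")
    templates = [t for t in make_default_templates() if t.name in EURASIAN5]
    spec = SyntheticCohortSpec(
        templates=tuple(templates), n_per_class=8, rng_seed=11
    )
    sample_cohort(spec, root / "modern")
    syl = [t for t in templates if t.name == SYLVESTRIS_TEMPLATE][0]
    rng = np.random.default_rng(12)
    (root / "fossil" / "images").mkdir(parents=True)
    rows = []
    for i in range(10):
        sid = f"fossil_{i:03d}"
        o = sample_outline(syl, rng, fossil_distortion=1.0, specimen_id=sid)
        _write_png(rasterize_outline(o), root / "fossil" / f"images/{sid}.png")
        rows.append(
            dict(specimen_id=sid, path=f"images/{sid}.png", group="unknown",
                 view="dorsal", dpi=600,
                 assemblage="A" if i < 7 else "B")
        )
    pd.DataFrame(rows).to_csv(root / "fossil" / "manifest.csv", index=False)
    return root
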