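"""Shared fixtures: small phantoms and independent brute-force oracles."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

import petmcc as m
from petmcc.phantom import _airway_seed


# ---------------------------------------------------------------------------
# Oracles (independent of the implementation paths they check)

def brute_force_depth(mask: np.ndarray, spacing) -> np.ndarray:
    """Per-voxel distance to the nearest background voxel center, computed by
    explicit nearest-neighbour search (KD-tree over background points,
    including a one-voxel border outside the grid)."""
    spacing = np.asarray(spacing, dtype=float)
    padded = np.pad(mask.astype(bool), 1)
    bg = np.argwhere(~padded) - 1  # back to original index frame
    fg = np.argwhere(mask.astype(bool))
    tree = cKDTree(bg * spacing)
    d, _ = tree.query(fg * spacing)
    out = np.zeros(mask.shape, dtype=float)
    out[tuple(fg.T)] = d
    return out


def fisher_exact_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins, using log-factorials only."""
    from math import lgamma, exp

    def lfact(n):
        return lgamma(n + 1)

    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lden = lfact(n) - (lfact(r1) + lfact(r2) + lfact(c1) + lfact(c2))

    def logp(x):
        # table (x, r1-x, c1-x, r2-c1+x)
        return -(lfact(x) + lfact(r1 - x) + lfact(c1 - x) + lfact(r2 - c1 + x)) - lden

    lo, hi = max(0, c1 - r2), min(r1, c1)
    lp_obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= lp_obs + 1e-9:
            total += exp(lp)
    return min(total, 1.0)


def f_sf_oracle(fstat: float, d1: int, d2: int) -> float:
    """Upper-tail F probability via the regularized incomplete beta function."""
    from scipy.special import betainc

    if fstat <= 0:
        return 1.0
    return float(betainc(d2 / 2.0, d1 / 2.0, d2 / (d2 + d1 * fstat)))


# ---------------------------------------------------------------------------
# Phantom fixtures (desk scale: small grid, full acquisition protocol)

def small_phantom_spec(**overrides) -> m.PhantomSpec:
    """A 72 mm thorax on a 72^3 1-mm grid; acquisition protocol unchanged."""
    kwargs = dict(
        tree=m.AirwayTreeSpec(root_radius_mm=2.0, root_length_mm=16.0, length_ratio=0.8),
        shape=(72, 72, 72),
        spacing_mm=(1.0, 1.0, 1.0),
        lung_semi_axes_mm=(24.0, 28.0, 32.0),
        body_margin_mm=4.0,
        noise=False,
        apply_psf=False,
        seed=1,
    )
    kwargs.update(overrides)
    return m.PhantomSpec(**kwargs)


def build_phantom(spec: m.PhantomSpec):
    """(branches, ct, labels, series, truth, airway_seed) for a spec."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        branches = m.generate_airway_tree(spec, np.random.default_rng(spec.seed))
    ct, labels = m.rasterize_ct(branches, spec)
    series, truth = m.simulate_dynamics(branches, spec)
    return branches, ct, labels, series, truth, _airway_seed(branches, spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noiseless, PSF-off phantom with the default (non-CF-like) kinetics."""
    spec = small_phantom_spec()
    return spec, *build_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Full physics: PSF blur + Poisson counting, seeded."""
    spec = small_phantom_spec(noise=True, apply_psf=True, seed=11)
    return spec, *build_phantom(spec)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A tiny on-disk two-group cohort (fast vs slow truth) with full physics."""
    out = tmp_path_factory.mktemp("cohort")
    spec = small_phantom_spec(noise=True, apply_psf=True, seed=5, shape=(56, 56, 56),
                              lung_semi_axes_mm=(19.0, 21.0, 24.0),
                              tree=m.AirwayTreeSpec(root_radius_mm=2.0,
                                                    root_length_mm=12.0,
                                                    length_ratio=0.8,
                                                    generations=5))
    groups = {
        "fast": m.KineticsSpec(f=0.15, k_fast=0.8, k_slow=0.011),
        "slow": m.KineticsSpec(f=0.08, k_fast=0.6, k_slow=0.006),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = m.make_cohort(spec, n_per_group=2, group_kinetics=groups,
                                 seed=5, out_dir=out, subject_jitter_sigma=0.1)
    return out, manifest
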