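"""Ground-truth structures and Hi-C-like contact maps for end-to-end tests.

Generators emulate the statistical structure the reconstruction assumes —
a chain-like curve confined to a territory, with contact likelihood falling
off with spatial distance — without attempting biophysical polymer realism.

Defaults mirror the modeled regime: unit step length along the chain, a
squared contact threshold of 7.0 and a confinement radius of 2.2 model
units, half the territory diameter sqrt(20) implied by the maximum
intra-chromosomal distance bound -- so a simulated truth satisfies every
model constraint and the contact fraction lands in the high range seen in
real 1 MB per-chromosome maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ContactMatrix
from .model import Structure

__all__ = [
    "SyntheticInstance",
    "simulate_structure",
    "contacts_from_structure",
    "make_instance",
    "matched_cutoff",
]

GENERATORS = ("random_walk", "helix", "two_blob")

_IF_INTENSITY = 100.0   # expected count at unit squared distance
_MIN_D2 = 0.25          # cap: squared distance floor for the 1/d^2 law


@dataclass
class SyntheticInstance:
    truth: Structure
    matrix: ContactMatrix      # raw counts
    generator: str
    noise: float
    seed: int


def _random_walk(n: int, rng: np.random.Generator, radius: float) -> np.ndarray:
    """Fixed-step walk reflected inside a sphere, avoiding close revisits.

    Steps of unit length in uniform random directions; a step leaving the
    confinement sphere or landing within 0.5 units of an earlier point is
    resampled (up to a bounded number of tries, then accepted as-is so the
    walk never stalls).
    """
    points = np.zeros((n, 3))
    for k in range(1, n):
        for _ in range(100):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = points[k - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            d = np.linalg.norm(points[: k - 1] - cand, axis=1) if k > 1 else np.array([1.0])
            if d.size and d.min() < 0.5:
                continue
            break
        points[k] = cand
    return points


def _helix(n: int, radius: float) -> np.ndarray:
    """Deterministic helix with equal consecutive-point spacing."""
    turns = max(n / 10.0, 1.0)
    t = np.linspace(0, 2 * np.pi * turns, n)
    r = min(1.0, radius / 2.0)
    pitch = r / 2.0
    return np.column_stack([r * np.cos(t), r * np.sin(t), pitch * t / (2 * np.pi)])


def _two_blob(n: int, rng: np.random.Generator, radius: float) -> np.ndarray:
    """Two dense clusters joined by a short linker, for compartment tests."""
    n1 = n // 2
    centers = np.array([[-radius / 2, 0, 0], [radius / 2, 0, 0]])
    pts = np.empty((n, 3))
    pts[:n1] = centers[0] + rng.normal(scale=0.4, size=(n1, 3))
    pts[n1:] = centers[1] + rng.normal(scale=0.4, size=(n - n1, 3))
    return pts


def simulate_structure(
    n: int,
    generator: str = "random_walk",
    seed: int = 0,
    confinement_radius: float = 2.2,
    chrom: str = "chrS",
    resolution: int = 1_000_000,
) -> Structure:
    """Simulate a ground-truth structure with one of the named generators."""
    if n < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    if generator == "random_walk":
        points = _random_walk(n, rng, confinement_radius)
    elif generator == "helix":
        points = _helix(n, confinement_radius)
    elif generator == "two_blob":
        points = _two_blob(n, rng, confinement_radius)
    else:
        raise ValueError(
            f"unknown generator {generator!r}; expected one of {GENERATORS}"
        )
    return Structure(points=points, chrom=chrom, resolution=resolution)


def contacts_from_structure(
    S: Structure,
    dc2: float = 7.0,
    if_model: str = "binary",
    noise: float = 0.0,
    seed: int = 0,
) -> ContactMatrix:
    """Derive a raw contact-count matrix from a known structure.

    ``binary`` sets count 1 for pairs with squared distance below ``dc2``
    and 0 otherwise, so downstream filtering can recover the true contact
    set exactly.  ``inverse_distance`` draws counts with expectation
    proportional to 1/d^2 (capped at short range); ``noise`` scales the
    Poisson mean downward (counts ~ Poisson(lambda / noise)), so larger
    values give sparser, noisier maps, and noise = 0 returns the exact
    expected counts deterministically.
    """
    if dc2 <= 0:
        raise ValueError("dc2 must be positive")
    n = S.n
    diff = S.points[:, None, :] - S.points[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    if if_model == "binary":
        values = (d2 < dc2).astype(float)
        np.fill_diagonal(values, 0.0)
    elif if_model == "inverse_distance":
        lam = _IF_INTENSITY / np.maximum(d2, _MIN_D2)
        np.fill_diagonal(lam, 0.0)
        if noise == 0.0:
            values = lam
        else:
            rng = np.random.default_rng(seed)
            iu, ju = np.triu_indices(n, k=1)
            draws = rng.poisson(lam[iu, ju] / noise).astype(float)
            values = np.zeros_like(lam)
            values[iu, ju] = draws
            values[ju, iu] = draws
    else:
        raise ValueError(f"unknown if_model {if_model!r}")
    return ContactMatrix(
        values=values, resolution=S.resolution, normalized=False, chrom=S.chrom
    )


def matched_cutoff(N: ContactMatrix, truth: Structure, dc2: float = 7.0) -> float:
    """Likelihood-ratio cutoff matching the truth's short-distance fraction.

    For graded (inverse-distance) IF fixtures, normalization reshuffles the
    within-row ordering of counts, so no universal cutoff value maps the IF
    scale back onto the distance threshold.  This calibration picks the
    normalized-IF quantile whose exceedance fraction equals the fraction of
    non-adjacent pair distances of the generating structure below ``dc2`` --
    the fixture analogue of choosing the cutoff against an independently
    known feature of the system.
    """
    if N.n != truth.n:
        raise ValueError("matrix and truth sizes differ")
    iu, ju = np.triu_indices(N.n, k=2)
    diff = truth.points[iu] - truth.points[ju]
    d2 = np.einsum("ij,ij->i", diff, diff)
    frac = float(np.mean(d2 < dc2))
    return float(np.quantile(N.values[iu, ju], 1.0 - frac))


def make_instance(
    n: int = 20,
    generator: str = "random_walk",
    dc2: float = 7.0,
    if_model: str = "binary",
    noise: float = 0.0,
    seed: int = 0,
    confinement_radius: float = 2.2,
) -> SyntheticInstance:
    """Bundle a simulated truth with its derived contact matrix.

    The standard fixture for optimizer, evaluation and robustness tests:
    structure and matrix share the instance seed, so an instance is a pure
    function of its arguments.
    """
    truth = simulate_structure(
        n, generator=generator, seed=seed, confinement_radius=confinement_radius
    )
    matrix = contacts_from_structure(
        truth, dc2=dc2, if_model=if_model, noise=noise, seed=seed + 1
    )
    return SyntheticInstance(
        truth=truth, matrix=matrix, generator=generator, noise=noise, seed=seed
    )
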