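"""Population mutation rate (theta = 4 Ne mu) from read-profile base counts.

At each genomic position the quartet of read base counts n = (nA, nC, nG, nT)
is a *profile*. A site is heterozygous with probability H = theta / (1 + theta)
(diploid, infinite-sites approximation). The composite likelihood treats sites
as independent and mixes two genotype classes with a symmetric read-error
model at rate eps:

    L(theta, eps) = prod_sites [ (1 - H) P(n | hom, eps) + H P(n | het, eps) ]

For a homozygous site each read shows the true base w.p. 1 - eps (else
uniform over the other three); for a heterozygous site each read shows either
allele w.p. (1 - eps)/2 + eps/6 and an off-genotype base w.p. eps/3, i.e. the
two allele counts are symmetric-binomial around half coverage adjusted for
eps. The unknown genotype is marginalised uniformly within each class. Theta
and eps are fit jointly by a grid search plus simplex refinement; the 95%
confidence interval comes from the profile likelihood at delta log-L = 1.92.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from .genome import ValidationError, WindowedTrack, compute_windowed_tracks


@dataclass(frozen=True)
class SiteProfile:
    """Read base counts (nA, nC, nG, nT) at one genomic position."""

    chromosome: str
    position: int
    counts: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValidationError("negative base count")

    @property
    def coverage(self) -> int:
        return sum(self.counts)


class ProfileSet:
    """A column-oriented collection of site profiles."""

    def __init__(
        self,
        counts: np.ndarray,
        chromosome: Sequence[str] | None = None,
        position: Sequence[int] | None = None,
    ):
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError("counts must be an N x 4 array")
        if (self.counts < 0).any():
            raise ValidationError("negative base count")
        n = len(self.counts)
        self.chromosome = np.asarray(
            chromosome if chromosome is not None else ["."] * n, dtype=object
        )
        self.position = np.asarray(
            position if position is not None else np.arange(n), dtype=np.int64
        )

    def __len__(self) -> int:
        return len(self.counts)

    def __iter__(self):
        for i in range(len(self)):
            yield SiteProfile(
                str(self.chromosome[i]), int(self.position[i]),
                tuple(int(c) for c in self.counts[i]),
            )

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ThetaEstimate:
    theta: float
    ci_low: float
    ci_high: float
    error_rate: float
    sites_used: int
    log_likelihood: float


@dataclass
class MutationRates:
    mu_per_generation: float
    mu_per_year: float
    ne: int
    generation_time: float


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_profiles(path: str | Path, min_depth: int = 4) -> ProfileSet:
    """Read a profile TSV (chromosome, position, nA, nC, nG, nT).

    Profiles with coverage below ``min_depth`` (default 4, the homozygous
    profile depth floor) are excluded.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chromosome", "position", "nA", "nC", "nG", "nT"],
            dtype={"chromosome": str}, comment="#",
        )
    except pd.errors.EmptyDataError:
        return ProfileSet(np.empty((0, 4), dtype=np.int64))
    counts = df[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.int64)
    if (counts < 0).any():
        raise ValidationError(f"{path}: negative base count")
    keep = counts.sum(axis=1) >= min_depth
    return ProfileSet(
        counts[keep],
        df["chromosome"].to_numpy()[keep],
        df["position"].to_numpy(dtype=np.int64)[keep],
    )


def write_profiles(profiles: ProfileSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(len(profiles)):
            c = profiles.counts[i]
            fh.write(
                f"{profiles.chromosome[i]}\t{profiles.position[i]}"
                f"\t{c[0]}\t{c[1]}\t{c[2]}\t{c[3]}\n"
            )


# ---------------------------------------------------------------------------
# Maximum-likelihood theta
# ---------------------------------------------------------------------------

def _collapse(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse N x 4 profiles to unique sorted count quartets with weights.

    Both genotype classes have base-exchangeable read models, so the sorted
    quartet is a sufficient summary and the (dropped) multinomial coefficient
    is a per-site constant.
    """
    srt = np.sort(counts, axis=1)[:, ::-1]
    uniq, w = np.unique(srt, axis=0, return_counts=True)
    return uniq.astype(float), w.astype(float)


def _loglik(theta: float, eps: float, uniq: np.ndarray, w: np.ndarray) -> float:
    """Composite log-likelihood over collapsed profiles (up to a constant).

    Per site: hom with the true base uniform over the 4 bases (each read
    correct w.p. 1 - eps, else uniform over the other three); het with the
    allele pair uniform over the 6 pairs (each read shows either allele w.p.
    (1 - eps)/2 + eps/6, an off-genotype base w.p. eps/3).
    """
    eps = max(eps, 1e-9)
    n = uniq.sum(axis=1)
    h = theta / (1.0 + theta)
    log_err = math.log(eps / 3.0)
    # hom: sum over which base is the true one
    log_correct = math.log1p(-eps)
    hom_terms = uniq * log_correct + (n[:, None] - uniq) * log_err  # (m, 4)
    log_hom = logsumexp(hom_terms, axis=1) + math.log(0.25)
    # het: sum over unordered allele pairs
    q = math.log((1.0 - eps) / 2.0 + eps / 6.0)
    pair_idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    het_terms = np.stack(
        [
            (uniq[:, i] + uniq[:, j]) * q + (n - uniq[:, i] - uniq[:, j]) * log_err
            for i, j in pair_idx
        ],
        axis=1,
    )
    log_het = logsumexp(het_terms, axis=1) + math.log(1.0 / 6.0)
    site = np.logaddexp(math.log1p(-h) + log_hom, math.log(h) + log_het)
    return float(np.dot(w, site))


def estimate_theta_ml(
    profiles: ProfileSet | np.ndarray,
    theta_bounds: tuple[float, float] = (1e-6, 0.2),
    eps_bounds: tuple[float, float] = (1e-5, 0.2),
) -> ThetaEstimate:
    """Joint ML fit of theta and the sequencing error rate.

    Optimisation is a log-space grid over (theta, eps) followed by
    Nelder-Mead refinement; the CI is the theta profile likelihood crossing
    ``max log-L - 1.92`` (chi-square 95%, one parameter), with eps
    re-optimised at each theta.
    """
    counts = profiles.counts if isinstance(profiles, ProfileSet) else np.asarray(profiles)
    if len(counts) == 0:
        raise ValidationError("no profiles supplied")
    uniq, w = _collapse(counts)

    if not (uniq[:, 1] > 0).any():
        warnings.warn("all profiles monomorphic; theta at lower optimisation bound")
        ll = _loglik(theta_bounds[0], eps_bounds[0], uniq, w)
        return ThetaEstimate(theta_bounds[0], theta_bounds[0], theta_bounds[0],
                             eps_bounds[0], int(len(counts)), ll)

    t_grid = np.geomspace(*theta_bounds, 48)
    e_grid = np.geomspace(*eps_bounds, 32)
    best = (-np.inf, t_grid[0], e_grid[0])
    for t in t_grid:
        for e in e_grid:
            ll = _loglik(t, e, uniq, w)
            if ll > best[0]:
                best = (ll, t, e)

    def neg(x: np.ndarray) -> float:
        t = float(np.clip(np.exp(x[0]), *theta_bounds))
        e = float(np.clip(np.exp(x[1]), *eps_bounds))
        return -_loglik(t, e, uniq, w)

    res = minimize(neg, np.log([best[1], best[2]]), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-7})
    theta_hat = float(np.clip(np.exp(res.x[0]), *theta_bounds))
    eps_hat = float(np.clip(np.exp(res.x[1]), *eps_bounds))
    ll_max = -float(res.fun)

    def profile_ll(t: float) -> float:
        r = minimize_scalar(
            lambda le: -_loglik(t, float(np.clip(np.exp(le), *eps_bounds)), uniq, w),
            bounds=(np.log(eps_bounds[0]), np.log(eps_bounds[1])), method="bounded",
            options={"xatol": 1e-4},
        )
        return -float(r.fun)

    target = ll_max - 1.92
    lo = _profile_root(profile_ll, theta_hat, theta_bounds[0], target, decreasing=True)
    hi = _profile_root(profile_ll, theta_hat, theta_bounds[1], target, decreasing=False)
    return ThetaEstimate(theta_hat, lo, hi, eps_hat, int(len(counts)), ll_max)


def _profile_root(
    f, theta_hat: float, bound: float, target: float, decreasing: bool
) -> float:
    """Bisect for the theta where the profile log-likelihood crosses target."""
    a, b = (bound, theta_hat) if decreasing else (theta_hat, bound)
    edge = f(bound)
    if edge >= target:
        return bound
    for _ in range(40):
        mid = np.sqrt(a * b)  # geometric bisection: theta spans decades
        if f(mid) >= target:
            if decreasing:
                b = mid
            else:
                a = mid
        else:
            if decreasing:
                a = mid
            else:
                b = mid
        if b / a < 1.001:
            break
    return float(b if decreasing else a)


# ---------------------------------------------------------------------------
# Rate conversions and heterozygosity
# ---------------------------------------------------------------------------

def mu_per_generation(theta: float, ne: int) -> float:
    """mu per site per generation = theta / (4 Ne)."""
    if ne <= 0:
        raise ValueError("ne must be positive")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return theta / (4.0 * ne)


def mu_per_year(mu_gen: float, generation_time: float) -> float:
    """mu per site per year = mu per generation / generation time (years)."""
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    return mu_gen / generation_time


def mutation_rates(theta: float, ne: int, generation_time: float) -> MutationRates:
    mg = mu_per_generation(theta, ne)
    return MutationRates(mg, mu_per_year(mg, generation_time), ne, generation_time)


def heterozygosity_summary(
    het_sites: Sequence[tuple[str, int]],
    effective_bases: Mapping[str, int],
    chromosome_lengths: Mapping[str, int],
    window_size: int = 1_000_000,
) -> tuple[float, dict[str, WindowedTrack]]:
    """Global heterozygosity (%) and per-window heterozygous-site counts.

    Global heterozygosity is total het sites over total unmasked bases,
    as a percentage; the per-megabase track counts het sites by position.
    """
    total_bases = sum(effective_bases.values())
    if total_bases <= 0:
        raise ValidationError("zero effective-base denominator")
    global_pct = 100.0 * len(het_sites) / total_bases
    tracks = compute_windowed_tracks(dict(chromosome_lengths), het_sites, window_size)
    return global_pct, tracks
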