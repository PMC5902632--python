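"""Toy adaptive half-harmonic (ratchet) biasing of a Watson-Crick -> Hoogsteen flip.

A desk-scale re-implementation of the adaptive biasing scheme used to drive
rare base-flipping transitions: a half-harmonic penalty

    W(rho) = alpha/2 * (rho - rho_a)^2   on the active branch, else 0

acts on a collective distance

    rho = 1/(N(N-1)) * sum_{i} sum_{j != i} (r_ij - r_ij^R)^2    [Angstrom^2]

between pseudo-atom pair distances r_ij and their values r_ij^R in the target
(Hoogsteen) structure, with rho_a a running extremum of rho.  Two ratchet
conventions ship behind a flag:

* ``toward_reference`` (default): rho_a is the running *minimum* and the
  penalty applies when rho > rho_a, ratcheting the system toward the
  reference (the standard ratchet-and-pawl construction);
* ``as_printed``: rho_a is the running *maximum* and the penalty applies when
  rho < rho_a, the literal reading of the published equations (which drives
  rho away from the reference).

This is an explicit toy: the "structure" is a smooth map from the glycosidic
flipping angle chi and base-opening angle theta (degrees) to a handful of
pseudo-atom distances, the unbiased energy is a two-well surface with minima
at the Watson-Crick and Hoogsteen states, and the dynamics are overdamped
Langevin.  There is no force field and no solvent; the module exercises the
biasing equations and the 50 x 50 landscape-binning analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import binned_statistic_2d

__all__ = [
    "ToyLandscape",
    "BiasState",
    "BiasTrajectory",
    "rho_collective",
    "bias_potential",
    "run_biased",
    "run_ensemble",
    "transition_fraction",
    "bin_landscape",
    "KB_KCAL",
]

KB_KCAL = 0.0019872041  # kcal / mol / K

#: per-ordered-pair amplitude (Angstrom) of the chi dependence and theta slope
#: of the toy distance map; 3 pseudo-atoms -> 6 ordered pairs (i, j), i != j.
_PAIR_AMP = np.array([1.8, 1.2, 0.9, 1.8, 1.2, 0.9])
_PAIR_THETA = np.array([0.6, -0.4, 0.3, 0.6, -0.4, 0.3])
_PAIR_REF = np.array([2.9, 3.4, 5.1, 2.9, 3.4, 5.1])  # r_ij^R at the target


@dataclass(frozen=True)
class ToyLandscape:
    """Two-well (chi, theta) surface with WC and HG minima.

    Energies in kcal/mol, angles in degrees.  The unbiased potential is a
    harmonic opening restraint minus two Gaussian wells; both well centers are
    local minima and the potential is bounded below.  The smooth pseudo-atom
    distance map reaches its reference values (rho = 0) at the Hoogsteen
    target.
    """

    chi_wc: float = -110.0
    theta_wc: float = 8.0
    chi_hg: float = 70.0
    theta_hg: float = 22.0
    depth_wc: float = 7.0  # kcal/mol
    depth_hg: float = 4.0
    width_chi: float = 30.0  # degrees
    width_theta: float = 14.0
    opening_k: float = 3.0  # kcal/mol per (30 deg)^2 of opening
    theta_rest: float = 15.0
    n_atoms: int = 3

    def _wrap(self, dchi: np.ndarray) -> np.ndarray:
        return (np.asarray(dchi) + 180.0) % 360.0 - 180.0

    def energy(self, chi, theta):
        """Unbiased interaction energy E(chi, theta), kcal/mol."""
        chi = np.asarray(chi, dtype=float)
        theta = np.asarray(theta, dtype=float)
        e = self.opening_k * ((theta - self.theta_rest) / 30.0) ** 2
        for c0, t0, d in (
            (self.chi_wc, self.theta_wc, self.depth_wc),
            (self.chi_hg, self.theta_hg, self.depth_hg),
        ):
            dc = self._wrap(chi - c0) / self.width_chi
            dt = (theta - t0) / self.width_theta
            e = e - d * np.exp(-(dc**2 + dt**2))
        return e

    def energy_grad(self, chi, theta):
        chi = np.asarray(chi, dtype=float)
        theta = np.asarray(theta, dtype=float)
        gchi = np.zeros_like(chi)
        gtheta = self.opening_k * 2.0 * (theta - self.theta_rest) / 30.0**2
        for c0, t0, d in (
            (self.chi_wc, self.theta_wc, self.depth_wc),
            (self.chi_hg, self.theta_hg, self.depth_hg),
        ):
            dc = self._wrap(chi - c0)
            dt = theta - t0
            g = np.exp(-((dc / self.width_chi) ** 2 + (dt / self.width_theta) ** 2))
            gchi = gchi + d * g * 2.0 * dc / self.width_chi**2
            gtheta = gtheta + d * g * 2.0 * dt / self.width_theta**2
        return gchi, gtheta

    def distances(self, chi, theta):
        """Pseudo-atom ordered-pair distances r_ij(chi, theta), shape (..., 6)."""
        dc = np.radians(self._wrap(np.asarray(chi, dtype=float) - self.chi_hg))
        dt = np.asarray(theta, dtype=float) - self.theta_hg
        dev = (1.0 - np.cos(dc))[..., None] * _PAIR_AMP + (dt / 50.0)[..., None] * _PAIR_THETA
        return _PAIR_REF + dev

    def reference_distances(self) -> np.ndarray:
        return _PAIR_REF.copy()

    def rho(self, chi, theta):
        """Collective distance rho(chi, theta) to the Hoogsteen reference, A^2."""
        r = self.distances(chi, theta)
        n = self.n_atoms
        return ((r - _PAIR_REF) ** 2).sum(axis=-1) / (n * (n - 1))

    def rho_grad(self, chi, theta):
        """(d rho/d chi, d rho/d theta), analytic."""
        chi = np.asarray(chi, dtype=float)
        theta = np.asarray(theta, dtype=float)
        dc = np.radians(self._wrap(chi - self.chi_hg))
        dt = theta - self.theta_hg
        dev = (1.0 - np.cos(dc))[..., None] * _PAIR_AMP + (dt / 50.0)[..., None] * _PAIR_THETA
        n = self.n_atoms
        pref = 2.0 / (n * (n - 1))
        ddev_dchi = np.sin(dc)[..., None] * _PAIR_AMP * (np.pi / 180.0)
        ddev_dtheta = np.broadcast_to(_PAIR_THETA / 50.0, dev.shape)
        return (
            pref * (dev * ddev_dchi).sum(axis=-1),
            pref * (dev * ddev_dtheta).sum(axis=-1),
        )

    def max_stiffness(self) -> float:
        """Rough curvature bound (kcal/mol/deg^2) used for the step-size check."""
        k_wells = 2.0 * max(self.depth_wc, self.depth_hg) / min(self.width_chi, self.width_theta) ** 2
        k_open = 2.0 * self.opening_k / 30.0**2
        return k_wells + k_open


def rho_collective(distances: Sequence[float], references: Sequence[float], n_atoms: int) -> float:
    """Collective squared-distance to a reference structure (Angstrom^2).

    ``distances`` and ``references`` list the N(N-1) ordered-pair values
    r_ij and r_ij^R with the diagonal (i = j) excluded; the prefactor is
    1/(N(N-1)).
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms: the 1/(N(N-1)) prefactor is undefined")
    r = np.asarray(distances, dtype=float)
    rr = np.asarray(references, dtype=float)
    expected = n_atoms * (n_atoms - 1)
    if r.shape != rr.shape or r.shape[-1] != expected:
        raise ValueError(f"expected {expected} ordered-pair distances, got {r.shape}")
    return float(((r - rr) ** 2).sum(axis=-1) / expected)


def bias_potential(rho: float, rho_a: float, alpha: float, direction: str = "toward_reference"):
    """Half-harmonic bias W(rho) and its gradient dW/drho.

    Active branch: rho < rho_a for ``as_printed`` (penalise falling below the
    running maximum), rho > rho_a for ``toward_reference`` (penalise rising
    above the running minimum).  W >= 0 always, and W = 0 on the inactive
    branch including the rho = rho_a boundary.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rho = np.asarray(rho, dtype=float)
    rho_a = np.asarray(rho_a, dtype=float)
    if direction == "as_printed":
        active = rho < rho_a
    elif direction == "toward_reference":
        active = rho > rho_a
    else:
        raise ValueError(f"unknown direction {direction!r}")
    d = np.where(active, rho - rho_a, 0.0)
    w = 0.5 * alpha * d**2
    grad = alpha * d
    if w.ndim == 0:
        return float(w), float(grad)
    return w, grad


@dataclass
class BiasState:
    """Running state of the adaptive bias."""

    rho: float
    rho_a: float
    alpha: float
    direction: str = "toward_reference"

    def update(self, rho: float) -> None:
        self.rho = rho
        if self.direction == "as_printed":
            self.rho_a = max(self.rho_a, rho)
        else:
            self.rho_a = min(self.rho_a, rho)


@dataclass
class BiasTrajectory:
    """Time series of a biased (or unbiased) toy run."""

    chi: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    rho_a: np.ndarray
    bias_energy: np.ndarray
    energy: np.ndarray  # unbiased interaction energy, excludes W
    seed: int
    dt: float
    temperature: float
    alpha: float
    direction: str
    reached_target: bool

    def __len__(self) -> int:
        return len(self.chi)


def _simulate_ensemble(
    landscape: ToyLandscape,
    alpha: float,
    seeds: Sequence[int],
    n_steps: int,
    dt: float,
    temperature: float,
    direction: str,
    start: tuple[float, float] | None,
    friction: float,
    capture_radius: tuple[float, float],
    stride: int,
):
    """Batched overdamped Langevin: all seeds advance in lock-step.

    Each walker draws its noise from its own seeded generator, so a given
    seed sees the same noise sequence at every alpha (paired comparison).
    """
    stiff = landscape.max_stiffness()
    if dt * stiff / friction > 0.5:
        raise ValueError(
            f"unstable step: dt*k/friction = {dt * stiff / friction:.2f} > 0.5; "
            f"reduce dt below {0.5 * friction / stiff:.3g}"
        )
    S = len(seeds)
    noise = np.stack(
        [np.random.default_rng(s).standard_normal((n_steps, 2)) for s in seeds], axis=1
    )  # (n_steps, S, 2)
    chi0, theta0 = start if start is not None else (landscape.chi_wc, landscape.theta_wc)
    chi = np.full(S, float(chi0))
    theta = np.full(S, float(theta0))
    rho = landscape.rho(chi, theta)
    rho_a = rho.copy()
    ratchet_max = direction == "as_printed"
    if direction not in ("as_printed", "toward_reference"):
        raise ValueError(f"unknown direction {direction!r}")
    noise_scale = np.sqrt(2.0 * KB_KCAL * temperature * dt / friction)
    n_rec = n_steps // stride + 1
    rec = {k: np.empty((S, n_rec)) for k in ("chi", "theta", "rho", "rho_a", "w", "e")}
    reached = np.zeros(S, dtype=bool)
    j = 0
    for i in range(n_steps + 1):
        rho = landscape.rho(chi, theta)
        rho_a = np.maximum(rho_a, rho) if ratchet_max else np.minimum(rho_a, rho)
        w, dw = bias_potential(rho, rho_a, alpha, direction)
        if i % stride == 0:
            rec["chi"][:, j] = chi
            rec["theta"][:, j] = theta
            rec["rho"][:, j] = rho
            rec["rho_a"][:, j] = rho_a
            rec["w"][:, j] = w
            rec["e"][:, j] = landscape.energy(chi, theta)
            j += 1
            d_chi = np.abs((chi - landscape.chi_hg + 180.0) % 360.0 - 180.0)
            reached |= (d_chi < capture_radius[0]) & (
                np.abs(theta - landscape.theta_hg) < capture_radius[1]
            )
        if i == n_steps:
            break
        gu_c, gu_t = landscape.energy_grad(chi, theta)
        gr_c, gr_t = landscape.rho_grad(chi, theta)
        chi = chi - dt / friction * (gu_c + dw * gr_c) + noise_scale * noise[i, :, 0]
        theta = theta - dt / friction * (gu_t + dw * gr_t) + noise_scale * noise[i, :, 1]
        if not (np.all(np.isfinite(chi)) and np.all(np.isfinite(theta))):
            raise FloatingPointError(
                f"trajectory blew up at step {i}; reduce dt (currently {dt})"
            )
    return rec, reached, j


def run_biased(
    landscape: ToyLandscape,
    alpha: float,
    n_steps: int = 20000,
    dt: float = 0.05,
    temperature: float = 300.0,
    seed: int = 0,
    direction: str = "toward_reference",
    start: tuple[float, float] | None = None,
    friction: float = 1.0,
    capture_radius: tuple[float, float] = (30.0, 15.0),
    stride: int = 10,
) -> BiasTrajectory:
    """Overdamped Langevin run on U + W with the adaptive ratchet update.

    x_{n+1} = x_n - (dt/friction) grad(U + W) + sqrt(2 kB T dt / friction) xi.
    rho_a follows the running extremum of rho per the chosen convention.  The
    run reports whether the Hoogsteen basin was reached (both angles within
    ``capture_radius`` of the target well at any recorded frame).  The
    reported energy excludes the bias.  The step size is checked against the
    landscape stiffness before the run.
    """
    rec, reached, j = _simulate_ensemble(
        landscape, alpha, [seed], n_steps, dt, temperature, direction, start,
        friction, capture_radius, stride,
    )
    return BiasTrajectory(
        chi=rec["chi"][0, :j], theta=rec["theta"][0, :j], rho=rec["rho"][0, :j],
        rho_a=rec["rho_a"][0, :j], bias_energy=rec["w"][0, :j], energy=rec["e"][0, :j],
        seed=seed, dt=dt, temperature=temperature, alpha=alpha,
        direction=direction, reached_target=bool(reached[0]),
    )


def run_ensemble(
    landscape: ToyLandscape,
    alpha: float,
    seeds: Sequence[int],
    **kwargs,
) -> list[BiasTrajectory]:
    """Batched :func:`run_biased` over many seeds (identical noise pairing)."""
    n_steps = kwargs.pop("n_steps", 20000)
    dt = kwargs.pop("dt", 0.05)
    temperature = kwargs.pop("temperature", 300.0)
    direction = kwargs.pop("direction", "toward_reference")
    start = kwargs.pop("start", None)
    friction = kwargs.pop("friction", 1.0)
    capture_radius = kwargs.pop("capture_radius", (30.0, 15.0))
    stride = kwargs.pop("stride", 10)
    if kwargs:
        raise TypeError(f"unexpected arguments {sorted(kwargs)}")
    rec, reached, j = _simulate_ensemble(
        landscape, alpha, list(seeds), n_steps, dt, temperature, direction, start,
        friction, capture_radius, stride,
    )
    return [
        BiasTrajectory(
            chi=rec["chi"][s, :j], theta=rec["theta"][s, :j], rho=rec["rho"][s, :j],
            rho_a=rec["rho_a"][s, :j], bias_energy=rec["w"][s, :j],
            energy=rec["e"][s, :j], seed=int(seed), dt=dt, temperature=temperature,
            alpha=alpha, direction=direction, reached_target=bool(reached[s]),
        )
        for s, seed in enumerate(seeds)
    ]


def transition_fraction(
    landscape: ToyLandscape, alpha: float, seeds: Sequence[int], **kwargs
) -> float:
    """Fraction of seeds whose run reaches the Hoogsteen basin."""
    trajs = run_ensemble(landscape, alpha, seeds, **kwargs)
    return sum(t.reached_target for t in trajs) / len(trajs)


def bin_landscape(
    trajectories: Sequence[BiasTrajectory],
    chi_range: tuple[float, float] = (-180.0, 180.0),
    theta_range: tuple[float, float] = (-30.0, 60.0),
    n_bins: int = 50,
) -> dict:
    """Mean unbiased energy on a fixed 50 x 50 (chi, theta) grid.

    Empty bins are NaN (missing), never zero.  Returns the grid, the bin
    edges, and per-bin counts.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    chi = np.concatenate([t.chi for t in trajectories])
    theta = np.concatenate([t.theta for t in trajectories])
    e = np.concatenate([t.energy for t in trajectories])
    chi = (chi + 180.0) % 360.0 - 180.0  # wrap into the declared range
    stat, xe, ye, _ = binned_statistic_2d(
        chi, theta, e, statistic="mean", bins=n_bins, range=[chi_range, theta_range]
    )
    counts, _, _, _ = binned_statistic_2d(
        chi, theta, e, statistic="count", bins=n_bins, range=[chi_range, theta_range]
    )
    return {"mean_energy": stat, "chi_edges": xe, "theta_edges": ye, "counts": counts}
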