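"""PGSE acquisition scheme representation, unit conversion, and shell clustering.

An acquisition is a per-measurement table of (b, G, n, delta, Delta, TE). The
three standard parameterizations are interconvertible through

    b = G^2 delta^2 gamma^2 (Delta - delta/3),      q = G delta gamma / (2 pi),

with gamma the proton gyromagnetic ratio, so a scheme can be built from
b-values, gradient strengths, or q-values. Measurements are grouped into
acquisition shells by single-linkage clustering of b within each unique
(delta, Delta, TE) stratum, so that equal-b measurements acquired with
different pulse timings are never merged into one shell.

All inputs are SI (s/m^2, T/m, 1/m, s); the printed summary uses clinical
units (s/mm^2, mT/m, ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .constants import (
    B0_THRESHOLD,
    DEFAULT_SHELL_DISTANCE,
    GYROMAGNETIC_RATIO,
    SI_TO_MS,
    SI_TO_MTM,
    SI_TO_SMM2,
)

__all__ = [
    "AcquisitionScheme",
    "ShellSummary",
    "MeasurementTable",
    "build_scheme_from_bvalues",
    "build_scheme_from_gradients",
    "build_scheme_from_qvalues",
    "cluster_shells",
    "summarize_scheme",
    "shell_probe",
]


@dataclass
class MeasurementTable:
    """Minimal per-measurement view consumed by signal models.

    Any object exposing these attributes (notably :class:`AcquisitionScheme`)
    can be handed to a compartment model's ``attenuation``.
    """

    bvalues: np.ndarray
    qvalues: np.ndarray
    gradient_strengths: np.ndarray
    directions: np.ndarray
    delta: np.ndarray
    Delta: np.ndarray
    TE: np.ndarray | None

    @property
    def tau(self) -> np.ndarray:
        return self.Delta - self.delta / 3.0

    def __len__(self) -> int:
        return len(self.bvalues)


@dataclass
class ShellSummary:
    shell_id: int
    b: float
    n_measurements: int
    delta: float
    Delta: float
    TE: float | None
    is_b0: bool = field(default=False)


class AcquisitionScheme(MeasurementTable):
    """A validated PGSE acquisition with derived q, tau and shell labels."""

    def __init__(self, bvalues, gradient_strengths, qvalues, directions,
                 delta, Delta, TE=None,
                 shell_distance: float = DEFAULT_SHELL_DISTANCE):
        super().__init__(
            bvalues=np.asarray(bvalues, dtype=float),
            qvalues=np.asarray(qvalues, dtype=float),
            gradient_strengths=np.asarray(gradient_strengths, dtype=float),
            directions=np.asarray(directions, dtype=float),
            delta=np.asarray(delta, dtype=float),
            Delta=np.asarray(Delta, dtype=float),
            TE=None if TE is None else np.asarray(TE, dtype=float),
        )
        self._validate()
        self.shell_indices, self.shells = cluster_shells(self, shell_distance)
        b0_shells = {s.shell_id for s in self.shells if s.is_b0}
        self.b0_mask = np.isin(self.shell_indices, list(b0_shells))

    # -- validation ------------------------------------------------------
    def _validate(self):
        n = len(self.bvalues)
        if self.directions.shape != (n, 3):
            raise ValueError(
                f"directions shape {self.directions.shape} does not match "
                f"{n} measurements")
        for name in ("delta", "Delta"):
            arr = getattr(self, name)
            if arr.shape not in ((), (n,)):
                raise ValueError(f"{name} must be scalar or length-{n}")
            setattr(self, name, np.broadcast_to(arr, (n,)).astype(float))
        if self.TE is not None:
            if self.TE.shape not in ((), (n,)):
                raise ValueError(f"TE must be scalar or length-{n}")
            self.TE = np.broadcast_to(self.TE, (n,)).astype(float)
            if np.any(self.TE < 0):
                raise ValueError("TE must be non-negative")
        if np.any(self.bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(self.delta < 0) or np.any(self.Delta < 0):
            raise ValueError("delta and Delta must be non-negative")
        if np.any(self.Delta - self.delta / 3.0 <= 0):
            raise ValueError("Delta must exceed delta/3 (positive tau)")
        norms = np.linalg.norm(self.directions, axis=1)
        weighted = self.bvalues > B0_THRESHOLD
        if np.any(np.abs(norms[weighted] - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted directions must be unit norm")
        # b0 rows may carry the FSL convention zero vector; normalize to +z.
        zero = (~weighted) & (norms < 1e-12)
        self.directions = self.directions.copy()
        self.directions[zero] = [0.0, 0.0, 1.0]
        bad_b0 = (~weighted) & (~zero) & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad_b0):
            raise ValueError("b0 directions must be unit norm or zero")

    # -- convenience -----------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return len(self.bvalues)

    @property
    def n_shells(self) -> int:
        return len(self.shells)

    @property
    def nonzero_shells(self) -> list[ShellSummary]:
        return [s for s in self.shells if not s.is_b0]

    def subset(self, mask) -> "AcquisitionScheme":
        """New scheme restricted to the masked measurements."""
        mask = np.asarray(mask)
        return AcquisitionScheme(
            self.bvalues[mask], self.gradient_strengths[mask],
            self.qvalues[mask], self.directions[mask],
            self.delta[mask], self.Delta[mask],
            None if self.TE is None else self.TE[mask])

    def summary(self) -> str:
        return summarize_scheme(self)

    def __repr__(self):
        return (f"AcquisitionScheme({self.n_measurements} measurements, "
                f"{self.n_shells} shells, {int(self.b0_mask.sum())} b0)")


# ---------------------------------------------------------------------------
# builders

def _common_checks(values, directions, delta, Delta, TE, name):
    values = np.asarray(values, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if values.ndim != 1:
        raise ValueError(f"{name} must be a 1-D array")
    if directions.shape[0] != len(values):
        raise ValueError(f"{name} and directions have mismatched lengths")
    if np.any(values < 0):
        raise ValueError(f"{name} must be non-negative")
    return values, directions


def build_scheme_from_bvalues(bvalues, directions, delta, Delta, TE=None,
                              shell_distance=DEFAULT_SHELL_DISTANCE):
    """Scheme from b [s/m^2]; G and q derived via the PGSE formulas."""
    bvalues, directions = _common_checks(
        bvalues, directions, delta, Delta, TE, "bvalues")
    delta_b = np.broadcast_to(np.asarray(delta, float), bvalues.shape)
    Delta_b = np.broadcast_to(np.asarray(Delta, float), bvalues.shape)
    tau = Delta_b - delta_b / 3.0
    if np.any(tau <= 0):
        raise ValueError("Delta must exceed delta/3")
    qvalues = np.sqrt(bvalues / tau) / (2 * np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(delta_b > 0,
                     2 * np.pi * qvalues / (delta_b * GYROMAGNETIC_RATIO), 0.0)
    return AcquisitionScheme(bvalues, G, qvalues, directions, delta, Delta, TE,
                             shell_distance)


def build_scheme_from_gradients(gradient_strengths, directions, delta, Delta,
                                TE=None, shell_distance=DEFAULT_SHELL_DISTANCE):
    """Scheme from G [T/m]; b and q derived."""
    G, directions = _common_checks(
        gradient_strengths, directions, delta, Delta, TE, "gradient_strengths")
    delta_b = np.broadcast_to(np.asarray(delta, float), G.shape)
    Delta_b = np.broadcast_to(np.asarray(Delta, float), G.shape)
    qvalues = G * delta_b * GYROMAGNETIC_RATIO / (2 * np.pi)
    bvalues = (2 * np.pi * qvalues) ** 2 * (Delta_b - delta_b / 3.0)
    return AcquisitionScheme(bvalues, G, qvalues, directions, delta, Delta, TE,
                             shell_distance)


def build_scheme_from_qvalues(qvalues, directions, delta, Delta, TE=None,
                              shell_distance=DEFAULT_SHELL_DISTANCE):
    """Scheme from q [1/m]; b and G derived."""
    q, directions = _common_checks(
        qvalues, directions, delta, Delta, TE, "qvalues")
    delta_b = np.broadcast_to(np.asarray(delta, float), q.shape)
    Delta_b = np.broadcast_to(np.asarray(Delta, float), q.shape)
    bvalues = (2 * np.pi * q) ** 2 * (Delta_b - delta_b / 3.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(delta_b > 0,
                     2 * np.pi * q / (delta_b * GYROMAGNETIC_RATIO), 0.0)
    return AcquisitionScheme(bvalues, G, q, directions, delta, Delta, TE,
                             shell_distance)


# ---------------------------------------------------------------------------
# shell clustering

def cluster_shells(scheme: MeasurementTable,
                   b_distance_threshold: float = DEFAULT_SHELL_DISTANCE):
    """Single-linkage clustering of b within each (delta, Delta, TE) stratum.

    Returns per-measurement integer labels (sorted by ascending shell b) and
    the corresponding :class:`ShellSummary` list. Deterministic and invariant
    to measurement order.
    """
    if b_distance_threshold <= 0:
        raise ValueError("b_distance_threshold must be positive")
    n = len(scheme.bvalues)
    TE = scheme.TE if scheme.TE is not None else np.zeros(n)
    timing = np.column_stack([
        np.broadcast_to(scheme.delta, (n,)),
        np.broadcast_to(scheme.Delta, (n,)),
        np.broadcast_to(TE, (n,)),
    ])
    # strata of identical timings (exact match; timings are protocol values)
    _, strata = np.unique(timing.round(12), axis=0, return_inverse=True)

    clusters = []  # (mean_b, delta, Delta, TE, member_indices)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        b = scheme.bvalues[idx]
        if len(idx) == 1:
            labels = np.array([1])
        else:
            order = np.argsort(b, kind="stable")  # permutation invariance
            z = linkage(b[order, None], method="single")
            lab_sorted = fcluster(z, t=b_distance_threshold,
                                  criterion="distance")
            labels = np.empty(len(idx), dtype=int)
            labels[order] = lab_sorted
        for lab in np.unique(labels):
            members = idx[labels == lab]
            clusters.append((
                float(scheme.bvalues[members].mean()),
                float(timing[members[0], 0]), float(timing[members[0], 1]),
                float(timing[members[0], 2]), members))

    clusters.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
    shell_indices = np.empty(n, dtype=int)
    shells = []
    for shell_id, (b_mean, d, D, te, members) in enumerate(clusters):
        shell_indices[members] = shell_id
        shells.append(ShellSummary(
            shell_id=shell_id, b=b_mean, n_measurements=len(members),
            delta=d, Delta=D, TE=te if scheme.TE is not None else None,
            is_b0=b_mean < B0_THRESHOLD))
    return shell_indices, shells


def summarize_scheme(scheme: AcquisitionScheme) -> str:
    """Human-readable scheme report in clinical units (storage stays SI)."""
    lines = [
        f"Acquisition scheme: {scheme.n_measurements} measurements, "
        f"{scheme.n_shells} shells "
        f"({len(scheme.nonzero_shells)} diffusion-weighted), "
        f"{int(scheme.b0_mask.sum())} b0 measurements",
        f"{'shell':>5} {'b [s/mm^2]':>11} {'N':>4} {'G [mT/m]':>9} "
        f"{'delta [ms]':>11} {'Delta [ms]':>11} {'TE [ms]':>8}",
    ]
    for s in scheme.shells:
        members = scheme.shell_indices == s.shell_id
        g = scheme.gradient_strengths[members].mean() * SI_TO_MTM
        te = "-" if s.TE is None else f"{s.TE * SI_TO_MS:.1f}"
        lines.append(
            f"{s.shell_id:>5} {s.b * SI_TO_SMM2:>11.1f} {s.n_measurements:>4} "
            f"{g:>9.2f} {s.delta * SI_TO_MS:>11.2f} "
            f"{s.Delta * SI_TO_MS:>11.2f} {te:>8}")
    return "\n".join(lines)


def shell_probe(shell: ShellSummary, directions: np.ndarray) -> MeasurementTable:
    """Measurement table replicating one shell's parameters at arbitrary
    directions — used for per-shell spherical quadrature of kernels."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    m = len(directions)
    tau = shell.Delta - shell.delta / 3.0
    q = np.sqrt(max(shell.b, 0.0) / tau) / (2 * np.pi)
    G = 0.0 if shell.delta == 0 else \
        2 * np.pi * q / (shell.delta * GYROMAGNETIC_RATIO)
    te = None if shell.TE is None else np.full(m, shell.TE)
    return MeasurementTable(
        bvalues=np.full(m, shell.b), qvalues=np.full(m, q),
        gradient_strengths=np.full(m, G), directions=directions,
        delta=np.full(m, shell.delta), Delta=np.full(m, shell.Delta), TE=te)
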