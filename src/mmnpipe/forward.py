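"""Analytic EEG forward model: dipoles in a three-shell spherical head.

The head is modelled as three concentric spherical shells (brain, skull,
scalp) with piecewise-constant conductivity.  The potential of a current
dipole is expanded in Legendre harmonics; for each harmonic degree the
radial coefficients are obtained by solving the interface continuity
conditions (potential and radial current density continuous, zero
current through the scalp surface).  The expansion basis is normalized
per shell so the linear systems stay well conditioned up to high degree.

Units contract: dipole moments in nAm, scalp potentials in µV.  All
potentials are returned re-expressed against the average of the scalp
EEG channels (average reference), which is also the reference frame of
the analysis chain downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ModelError, NumericalError
from .montage import ElectrodeMontage

logger = logging.getLogger(__name__)

#: nAm -> Am and V -> µV combined
_UNIT_SCALE = 1e-9 * 1e6


@dataclass(frozen=True)
class HeadModel:
    """Three-shell concentric spherical volume conductor.

    Defaults: brain/skull/scalp outer radii 71/79/85 mm with
    conductivities 0.33/0.0042/0.33 S/m (standard literature values) and
    a 60-term harmonic expansion.
    """

    shell_radii: tuple[float, float, float] = (0.071, 0.079, 0.085)
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)
    series_truncation: int = 60

    def __post_init__(self) -> None:
        r = self.shell_radii
        if not (0 < r[0] < r[1] < r[2]):
            raise DomainError("shell radii must be strictly increasing and positive")
        if any(c <= 0 for c in self.conductivities):
            raise DomainError("conductivities must be positive")
        if self.series_truncation < 20:
            raise DomainError("series truncation must be at least 20 terms")

    @property
    def brain_radius(self) -> float:
        return self.shell_radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.shell_radii[2]


@dataclass(frozen=True)
class DipoleSource:
    """A single current dipole strictly inside the brain shell."""

    location: np.ndarray  # (3,) meters, head frame
    moment: np.ndarray  # (3,) nAm

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", np.asarray(self.location, float))
        object.__setattr__(self, "moment", np.asarray(self.moment, float))


@dataclass(frozen=True)
class RegionalSource:
    """A regional source: one location carrying three orthonormal dipoles."""

    label: str
    location: np.ndarray  # (3,) meters
    orientations: np.ndarray = field(
        default_factory=lambda: np.eye(3)
    )  # rows are unit vectors

    def __post_init__(self) -> None:
        object.__setattr__(self, "location", np.asarray(self.location, float))
        ori = np.asarray(self.orientations, float)
        object.__setattr__(self, "orientations", ori)
        if not np.allclose(ori @ ori.T, np.eye(3), atol=1e-10):
            raise DomainError(
                f"orientations of {self.label} must be orthonormal within 1e-10"
            )


@dataclass(frozen=True)
class LeadfieldMatrix:
    """Gain matrix, channels x (3 per regional source), µV per nAm.

    Rows are average-referenced over the scalp EEG channels (the EOG row
    carries the same reference but does not enter the reference mean).
    """

    gains: np.ndarray
    channel_order: tuple[str, ...]
    source_order: tuple[str, ...]
    eeg_mask: np.ndarray
    condition_number: float

    @property
    def eeg_gains(self) -> np.ndarray:
        return self.gains[self.eeg_mask]


def _radial_coefficients(head: HeadModel, n_max: int) -> np.ndarray:
    """Scalp-surface harmonic transfer coefficients ``S[n]``, n = 1..n_max.

    ``S[n]`` is defined so that a dipole term with primary (infinite
    medium) potential ``c * r**-(n+1)`` inside the brain shell produces
    the scalp-surface potential ``S[n] * c`` (radii normalized to the
    scalp radius).
    """
    a1, a2, a3 = np.asarray(head.shell_radii) / head.scalp_radius  # a3 == 1
    s1, s2, s3 = head.conductivities
    S = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        np1 = n + 1
        r12 = (a1 / a2) ** n  # growing term of shell 2 evaluated at a1
        d21 = (a1 / a2) ** np1  # decaying term of shell 2 evaluated at a2
        r23 = a2**n
        # unknowns: [A1, A2, B2, A3, B3] with shell parametrization
        #   V1 = A1 (r/a1)^n + (r/a1)^-(n+1)          (primary coeff. 1)
        #   V2 = A2 (r/a2)^n + B2 (r/a1)^-(n+1)
        #   V3 = A3 r^n      + B3 (r/a2)^-(n+1)
        M = np.array(
            [
                [1.0, -r12, -1.0, 0.0, 0.0],
                [s1 * n, -s2 * n * r12, s2 * np1, 0.0, 0.0],
                [0.0, 1.0, d21, -r23, -1.0],
                [0.0, s2 * n, -s2 * np1 * d21, -s3 * n * r23, s3 * np1],
                [0.0, 0.0, 0.0, n, -np1 * a2**np1],
            ]
        )
        rhs = np.array([-1.0, s1 * np1, 0.0, 0.0, 0.0])
        A1, A2, B2, A3, B3 = np.linalg.solve(M, rhs)
        # scaled primary coefficient 1 corresponds to a true coefficient
        # a1^(n+1) in globally normalized radii
        S[n] = (A3 + B3 * a2**np1) / a1**np1
    return S


def potentials_at(
    head: HeadModel, dipole: DipoleSource, positions: np.ndarray
) -> np.ndarray:
    """Unreferenced scalp-surface potentials (µV) of one dipole.

    ``positions`` is an (n, 3) array of electrode sites on (or scaled
    onto) the scalp surface.  Used directly when simulating a recording
    against a physical reference electrode; analysis code should use
    :func:`dipole_potential`, which applies the average reference.
    """
    loc = dipole.location
    b = float(np.linalg.norm(loc))
    if b >= head.brain_radius:
        raise DomainError(
            f"dipole at |r| = {b * 1e3:.1f} mm is not strictly inside the "
            f"brain shell ({head.brain_radius * 1e3:.1f} mm)"
        )
    R = head.scalp_radius
    N = head.series_truncation
    f = b / R
    # crude tail bound relative to the leading term of the expansion
    tail = (2 * N + 1) * f ** (N - 1) / 3.0
    if tail > 1e-6:
        raise NumericalError(
            f"harmonic series not converged at {N} terms for dipole "
            f"eccentricity {b / head.brain_radius:.2f} "
            f"(tail estimate {tail:.1e}); increase series_truncation"
        )
    S = _radial_coefficients(head, N)

    moment = dipole.moment
    if b > 1e-12:
        rhat = loc / b
    else:
        # central dipole: only n = 1 survives; any radial frame works
        mn = np.linalg.norm(moment)
        rhat = moment / mn if mn > 0 else np.array([0.0, 0.0, 1.0])
    m_r = float(moment @ rhat)

    pos = np.atleast_2d(positions)
    ehat = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    x = np.clip(ehat @ rhat, -1.0, 1.0)
    sin_g = np.sqrt(np.maximum(0.0, 1.0 - x**2))
    # unit vector from the dipole axis toward each electrode (tangential)
    that = ehat - x[:, None] * rhat[None, :]
    norm = np.where(sin_g > 1e-12, sin_g, 1.0)
    that = that / norm[:, None]
    m_t = np.where(sin_g > 1e-12, that @ moment, 0.0)

    # Legendre P_n(x) and the derivative-based P_n^1 via recurrences
    n_el = len(x)
    P = np.zeros((N + 1, n_el))
    dP = np.zeros((N + 1, n_el))
    P[0] = 1.0
    P[1] = x
    dP[1] = 1.0
    for n in range(1, N):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    pn1 = sin_g[None, :] * dP  # positive-convention associated Legendre

    ns = np.arange(1, N + 1)
    radial_w = S[1:] * f ** (ns - 1)  # per-degree weight
    series = (radial_w * ns) @ P[1:] * m_r + (radial_w @ pn1[1:]) * m_t

    return series / (4.0 * np.pi * head.conductivities[0] * R**2) * _UNIT_SCALE


def dipole_potential(
    head: HeadModel, dipole: DipoleSource, montage: ElectrodeMontage
) -> np.ndarray:
    """Average-referenced scalp potentials (µV) of one dipole.

    Returns one value per montage channel.  The potential is linear in
    the dipole moment and the mean over the scalp EEG channels is zero;
    the EOG channel carries its own potential in the same reference but
    does not enter the reference mean.
    """
    v = potentials_at(head, dipole, montage.positions)
    return v - v[montage.eeg_mask].mean()


def regional_leadfield(
    head: HeadModel, source: RegionalSource, montage: ElectrodeMontage
) -> np.ndarray:
    """Channels x 3 gain block: column k is the potential of a unit
    1 nAm dipole along orientation k of the regional source."""
    cols = [
        dipole_potential(head, DipoleSource(source.location, ori), montage)
        for ori in source.orientations
    ]
    return np.column_stack(cols)


def assemble_leadfield(
    head: HeadModel,
    sources: list[RegionalSource],
    montage: ElectrodeMontage,
) -> LeadfieldMatrix:
    """Horizontal concatenation of regional gain blocks with a rank check."""
    if not sources:
        raise ModelError("at least one regional source is required")
    blocks = [regional_leadfield(head, s, montage) for s in sources]
    gains = np.hstack(blocks)
    eeg_mask = montage.eeg_mask
    sv = np.linalg.svd(gains[eeg_mask], compute_uv=False)
    rank = int((sv > sv[0] * 1e-10).sum())
    if rank < gains.shape[1]:
        raise ModelError(
            "assembled lead field is rank deficient (rank "
            f"{rank} < {gains.shape[1]}) for sources "
            f"{[s.label for s in sources]}"
        )
    cond = float(sv[0] / sv[-1])
    logger.info(
        "lead field assembled: %d channels x %d components, condition number %.2f",
        gains.shape[0], gains.shape[1], cond,
    )
    return LeadfieldMatrix(
        gains=gains,
        channel_order=montage.channel_names,
        source_order=tuple(s.label for s in sources),
        eeg_mask=eeg_mask,
        condition_number=cond,
    )
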