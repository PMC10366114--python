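"""Source definition and sampling: mixed neutron/photon beams.

A :class:`SourceSpec` combines a particle mix, a spatial distribution (point,
uniform disc, or the rotationally symmetric annular profile that mimics a
BNCT beam port), an angular distribution (monodirectional, cosine-weighted
about an axis, or isotropic), and per-particle-type grouped energy spectra.
Within a sampled group the energy is drawn log-uniformly (flat in lethargy)
by default.

The clinical head-and-neck beam used throughout the package is the grouped
spectrum 1% thermal (< 1 eV), 98% epithermal (1 eV - 0.1 MeV), 1% fast
(> 0.1 MeV, capped at the 20 MeV library maximum): :func:`head_neck_beam`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EnergyGroups",
    "PointSpatial",
    "DiscSpatial",
    "AnnulusSpatial",
    "Monodirectional",
    "CosineAbout",
    "Isotropic",
    "SourceSpec",
    "head_neck_beam",
    "sample_source",
    "sample_energies",
    "empirical_spectrum_fractions",
    "source_from_dict",
]

EPITHERMAL_BOUNDS_EV = (1.0, 1e5)  # thermal < 1 eV; fast > 0.1 MeV


def _unit(v) -> tuple[float, float, float]:
    n = math.sqrt(sum(x * x for x in v))
    if n == 0:
        raise ValueError("zero direction vector")
    return tuple(x / n for x in v)


def _orthonormal_basis(w):
    """Two unit vectors spanning the plane normal to unit vector w."""
    if abs(w[0]) < 0.9:
        a = (1.0, 0.0, 0.0)
    else:
        a = (0.0, 1.0, 0.0)
    u = (w[1] * a[2] - w[2] * a[1], w[2] * a[0] - w[0] * a[2], w[0] * a[1] - w[1] * a[0])
    u = _unit(u)
    v = (w[1] * u[2] - w[2] * u[1], w[2] * u[0] - w[0] * u[2], w[0] * u[1] - w[1] * u[0])
    return u, v


@dataclass(frozen=True)
class EnergyGroups:
    """Group histogram: (E_low, E_high, probability) triples, eV.

    Groups must be non-overlapping, ascending, with probabilities summing
    to 1.  ``shape`` fixes the within-group law: "log-uniform" (default) or
    "uniform".
    """

    groups: tuple[tuple[float, float, float], ...]
    shape: str = "log-uniform"

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups",
                           tuple((float(a), float(b), float(p)) for a, b, p in self.groups))
        if self.shape not in ("log-uniform", "uniform"):
            raise ValueError(f"unknown in-group shape {self.shape!r}")
        prev_hi = 0.0
        total = 0.0
        for lo, hi, p in self.groups:
            if not 0 < lo < hi:
                raise ValueError(f"bad group bounds ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError("energy groups overlap or are out of order")
            if p < 0:
                raise ValueError("negative group probability")
            prev_hi = hi
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group probabilities sum to {total}, not 1")


@dataclass(frozen=True)
class PointSpatial:
    point: tuple[float, float, float]


@dataclass(frozen=True)
class DiscSpatial:
    """Uniform over a disc of given radius, in the plane normal to ``normal``."""

    center: tuple[float, float, float]
    radius: float
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")
        object.__setattr__(self, "normal", _unit(self.normal))


@dataclass(frozen=True)
class AnnulusSpatial:
    """Rotationally symmetric about ``axis``: radius from a histogram profile.

    ``radial_bins`` are (r_low, r_high, probability) triples; within a bin
    the radius is drawn uniform in area (r^2).  The azimuth is uniform on
    [0, 2*pi); the point lies in the plane through ``center`` normal to the
    axis.
    """

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radial_bins: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _unit(self.axis))
        object.__setattr__(self, "radial_bins",
                           tuple((float(a), float(b), float(p)) for a, b, p in self.radial_bins))
        total = sum(p for _, _, p in self.radial_bins)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"radial bin probabilities sum to {total}, not 1")
        for lo, hi, p in self.radial_bins:
            if lo < 0 or hi <= lo or p < 0:
                raise ValueError(f"bad radial bin ({lo}, {hi}, {p})")


@dataclass(frozen=True)
class Monodirectional:
    direction: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", _unit(self.direction))


@dataclass(frozen=True)
class CosineAbout:
    """Cosine-weighted emission about an axis (pdf proportional to cos theta)."""

    axis: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "axis", _unit(self.axis))


@dataclass(frozen=True)
class Isotropic:
    pass


@dataclass(frozen=True)
class SourceSpec:
    particle_mix: tuple[tuple[str, float], ...]  # (type, probability)
    spatial: PointSpatial | DiscSpatial | AnnulusSpatial
    angular: Monodirectional | CosineAbout | Isotropic
    energy: dict[str, EnergyGroups] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "particle_mix",
                           tuple((t, float(p)) for t, p in self.particle_mix))
        total = sum(p for _, p in self.particle_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"particle-mix probabilities sum to {total}, not 1")
        for ptype, _ in self.particle_mix:
            if ptype not in ("neutron", "photon"):
                raise ValueError(f"unknown particle type {ptype!r}")
            if ptype not in self.energy:
                raise ValueError(f"no energy spectrum for particle type {ptype!r}")


def head_neck_beam(
    center=(-0.1, 0.0, 0.0),
    direction=(1.0, 0.0, 0.0),
    radius: float = 3.0,
) -> SourceSpec:
    """The clinical neutron beam: 1% thermal / 98% epithermal / 1% fast.

    A monodirectional uniform disc aimed along ``direction`` (the clinical
    irradiation is side-on, right to left).  Group boundaries are 1 eV and
    0.1 MeV; thermal extends down to 0.01 eV and fast up to the 20 MeV
    library ceiling.
    """
    groups = EnergyGroups(groups=(
        (1e-2, 1.0, 0.01),
        (1.0, 1e5, 0.98),
        (1e5, 2e7, 0.01),
    ))
    return SourceSpec(
        particle_mix=(("neutron", 1.0),),
        spatial=DiscSpatial(center=tuple(center), radius=radius, normal=tuple(direction)),
        angular=Monodirectional(direction=tuple(direction)),
        energy={"neutron": groups},
    )


# ---------------------------------------------------------------------------
# sampling


def _sample_group_energy(groups: EnergyGroups, rng) -> float:
    xi = rng.random()
    acc = 0.0
    lo, hi = groups.groups[-1][:2]
    for glo, ghi, p in groups.groups:
        acc += p
        if xi < acc:
            lo, hi = glo, ghi
            break
    u = rng.random()
    if groups.shape == "log-uniform":
        return lo * (hi / lo) ** u
    return lo + u * (hi - lo)


def _sample_position(spatial, rng) -> list[float]:
    if isinstance(spatial, PointSpatial):
        return list(spatial.point)
    if isinstance(spatial, DiscSpatial):
        r = spatial.radius * math.sqrt(rng.random())
        phi = 2.0 * math.pi * rng.random()
        u, v = _orthonormal_basis(spatial.normal)
        c = spatial.center
        return [c[ax] + r * (math.cos(phi) * u[ax] + math.sin(phi) * v[ax]) for ax in range(3)]
    if isinstance(spatial, AnnulusSpatial):
        xi = rng.random()
        acc = 0.0
        lo, hi = spatial.radial_bins[-1][:2]
        for blo, bhi, p in spatial.radial_bins:
            acc += p
            if xi < acc:
                lo, hi = blo, bhi
                break
        r = math.sqrt(lo * lo + rng.random() * (hi * hi - lo * lo))
        phi = 2.0 * math.pi * rng.random()
        u, v = _orthonormal_basis(spatial.axis)
        c = spatial.center
        return [c[ax] + r * (math.cos(phi) * u[ax] + math.sin(phi) * v[ax]) for ax in range(3)]
    raise TypeError(f"unknown spatial distribution {spatial!r}")


def _sample_direction(angular, rng) -> list[float]:
    if isinstance(angular, Monodirectional):
        return list(angular.direction)
    if isinstance(angular, Isotropic):
        mu = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - mu * mu))
        return [s * math.cos(phi), s * math.sin(phi), mu]
    if isinstance(angular, CosineAbout):
        mu = math.sqrt(rng.random())
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - mu * mu))
        u, v = _orthonormal_basis(angular.axis)
        w = angular.axis
        return [mu * w[ax] + s * (math.cos(phi) * u[ax] + math.sin(phi) * v[ax])
                for ax in range(3)]
    raise TypeError(f"unknown angular distribution {angular!r}")


def sample_source(spec: SourceSpec, rng):
    """Draw one source particle; returns a transport ParticleState."""
    from .transport import ParticleState  # local import to avoid a cycle

    xi = rng.random()
    acc = 0.0
    ptype = spec.particle_mix[-1][0]
    for t, p in spec.particle_mix:
        acc += p
        if xi < acc:
            ptype = t
            break
    position = _sample_position(spec.spatial, rng)
    direction = _sample_direction(spec.angular, rng)
    energy = _sample_group_energy(spec.energy[ptype], rng)
    return ParticleState(ptype=ptype, position=position, direction=direction, energy=energy)


def sample_energies(spec: SourceSpec, ptype: str, n: int, rng) -> np.ndarray:
    """Vectorized draw of ``n`` source energies for one particle type."""
    groups = spec.energy[ptype]
    probs = np.array([p for _, _, p in groups.groups])
    lows = np.array([lo for lo, _, _ in groups.groups])
    highs = np.array([hi for _, hi, _ in groups.groups])
    idx = rng.choice(len(probs), size=n, p=probs / probs.sum())
    u = rng.random(n)
    lo, hi = lows[idx], highs[idx]
    if groups.shape == "log-uniform":
        return lo * (hi / lo) ** u
    return lo + u * (hi - lo)


def empirical_spectrum_fractions(
    spec: SourceSpec,
    n_samples: int,
    boundaries,
    rng,
    ptype: str = "neutron",
) -> np.ndarray:
    """Sampled fraction of source particles per energy band.

    ``boundaries`` (eV, ascending) split the energy axis into
    len(boundaries)+1 bands; returns the fraction of ``n_samples`` sampled
    energies in each.  Used to validate a source definition against its
    configured group probabilities (e.g. the thermal/epithermal/fast split
    at boundaries 1 eV and 0.1 MeV).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    energies = sample_energies(spec, ptype, n_samples, rng)
    edges = np.concatenate(([-np.inf], np.asarray(boundaries, dtype=float), [np.inf]))
    counts, _ = np.histogram(energies, bins=edges)
    return counts / float(n_samples)


# ---------------------------------------------------------------------------
# config-dict construction (mirrors the run-config source block)


def source_from_dict(d: dict) -> SourceSpec:
    """Build a SourceSpec from the run configuration's source block."""
    sp = d["spatial"]
    kind = sp["type"]
    if kind == "point":
        spatial = PointSpatial(point=tuple(sp["point"]))
    elif kind == "disc":
        spatial = DiscSpatial(center=tuple(sp["center"]), radius=float(sp["radius"]),
                              normal=tuple(sp["normal"]))
    elif kind == "annulus-rotational":
        spatial = AnnulusSpatial(center=tuple(sp["center"]), axis=tuple(sp["axis"]),
                                 radial_bins=tuple(tuple(b) for b in sp["radial_bins"]))
    else:
        raise ValueError(f"unknown spatial type {kind!r}")
    an = d["angular"]
    kind = an["type"]
    if kind == "monodirectional":
        angular = Monodirectional(direction=tuple(an["direction"]))
    elif kind == "cosine-about":
        angular = CosineAbout(axis=tuple(an["axis"]))
    elif kind == "isotropic":
        angular = Isotropic()
    else:
        raise ValueError(f"unknown angular type {kind!r}")
    energy = {
        ptype: EnergyGroups(groups=tuple(tuple(g) for g in block["groups"]),
                            shape=block.get("shape", "log-uniform"))
        for ptype, block in d["energy"].items()
    }
    mix = tuple((p["type"], float(p["prob"])) for p in d["particles"])
    return SourceSpec(particle_mix=mix, spatial=spatial, angular=angular, energy=energy)
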