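"""Pointwise cross-section tables, materials, and the synthetic library.

A nuclide table holds, on one strictly ascending energy grid, the total
microscopic cross section sigma_total(E) (barns), its reaction partials
(neutron: elastic + capture; photon: photoelectric + compton + pair), and a
heating number H(E) (MeV): the average energy deposited locally per collision.
The track-length dose response of a material is then

    D(E) = phi(E) * sum_i rho_i * sigma_i(E) * H_i(E)

with rho_i the nuclide number density in atoms/(barn*cm), so rho*sigma is a
macroscopic cross section in 1/cm.

No real evaluated nuclear data is read.  :func:`make_synthetic_library` builds
tables from simple functional forms (constant, one-over-v, log-Gaussian
resonance bump) that satisfy every structural invariant of a real pointwise
library — which is all the transport and tally algorithms ever rely on.
Libraries round-trip through an HDF5 container (:func:`write_library` /
:func:`read_library`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np

from .energy_search import HashIndex, OpCounter, binary_interval, build_hash_index, hash_interval

__all__ = [
    "AVOGADRO",
    "BORON10",
    "PAIR_THRESHOLD_EV",
    "NEUTRON_REACTIONS",
    "PHOTON_REACTIONS",
    "EnergyGrid",
    "NuclideData",
    "Material",
    "VACUUM",
    "MacroBundle",
    "Library",
    "LibraryFormatError",
    "interpolate_xs",
    "macro_xs",
    "build_material",
    "make_synthetic_library",
    "toy_tissue_spec",
    "write_library",
    "read_library",
]

AVOGADRO = 6.02214076e23
BORON10 = "B10"
PAIR_THRESHOLD_EV = 1.022e6  # two electron rest masses

NEUTRON_REACTIONS = ("elastic", "capture")
PHOTON_REACTIONS = ("photoelectric", "compton", "pair")
_REACTIONS = {"neutron": NEUTRON_REACTIONS, "photon": PHOTON_REACTIONS}

# isotopic molar masses, g/mol
MOLAR_MASS = {"H1": 1.008, "C12": 12.000, "N14": 14.003, "O16": 15.995, "B10": 10.013}

LIBRARY_FORMAT_VERSION = "voxdose-library-1"


class LibraryFormatError(RuntimeError):
    """Raised when a library container is missing required structure."""


@dataclass(frozen=True)
class EnergyGrid:
    """Strictly ascending, positive, finite particle energies in eV."""

    nodes: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=np.float64)
        object.__setattr__(self, "nodes", nodes)
        if nodes.ndim != 1 or len(nodes) < 2:
            raise ValueError("energy grid needs at least 2 nodes")
        if not np.all(np.isfinite(nodes)) or not np.all(nodes > 0):
            raise ValueError("energy grid nodes must be finite and positive")
        if not np.all(np.diff(nodes) > 0):
            raise ValueError("energy grid nodes must be strictly increasing")

    @property
    def emin(self) -> float:
        return float(self.nodes[0])

    @property
    def emax(self) -> float:
        return float(self.nodes[-1])


@dataclass
class NuclideData:
    """One nuclide's pointwise tables for one transported particle type."""

    name: str
    particle: str  # "neutron" | "photon"
    mass_ratio_A: float  # target mass / neutron mass
    grid: EnergyGrid
    sigma_total: np.ndarray  # barns
    partials: dict[str, np.ndarray]  # reaction -> barns
    heating_H: np.ndarray  # MeV deposited per collision
    capture_gamma_energy: float = 0.0  # MeV; 0 = no capture photon
    index: HashIndex = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.particle not in _REACTIONS:
            raise ValueError(f"unknown particle type {self.particle!r}")
        n = len(self.grid.nodes)
        self.sigma_total = np.asarray(self.sigma_total, dtype=np.float64)
        self.heating_H = np.asarray(self.heating_H, dtype=np.float64)
        self.partials = {r: np.asarray(s, dtype=np.float64) for r, s in self.partials.items()}
        for label, arr in [("sigma_total", self.sigma_total), ("heating_H", self.heating_H),
                           *self.partials.items()]:
            if arr.shape != (n,):
                raise ValueError(f"{self.name}: array {label} length {arr.shape} != grid length {n}")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{self.name}: array {label} must be finite and nonnegative")
        unknown = set(self.partials) - set(_REACTIONS[self.particle])
        if unknown:
            raise ValueError(f"{self.name}: unknown reactions {sorted(unknown)}")
        total = sum(self.partials.values())
        scale = np.maximum(np.abs(self.sigma_total), 1e-300)
        if np.any(np.abs(total - self.sigma_total) / scale > 1e-9):
            raise ValueError(f"{self.name}: sigma_total != sum of partials beyond 1e-9 relative")
        if self.particle == "photon" and "pair" in self.partials:
            below = self.grid.nodes < PAIR_THRESHOLD_EV
            if np.any(self.partials["pair"][below] > 0):
                raise ValueError(
                    f"{self.name}: pair-production partial nonzero below {PAIR_THRESHOLD_EV} eV"
                )
        self.index = build_hash_index(self.grid.nodes)


@dataclass(frozen=True)
class Material:
    """A voxel-fillable material: number densities per nuclide.

    ``components`` are (nuclide name, rho) pairs with rho in atoms/(barn*cm).
    The reserved vacuum material has no components and zero mass density;
    every other material must have positive mass density.
    """

    id: int
    name: str
    components: tuple[tuple[str, float], ...]
    mass_density: float  # g/cm^3
    boron10_ppm: float = 0.0  # mass ppm of B-10, informational

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple((n, float(r)) for n, r in self.components))
        if any(r < 0 for _, r in self.components):
            raise ValueError(f"material {self.name!r}: negative number density")
        if self.components and self.mass_density <= 0:
            raise ValueError(f"material {self.name!r}: mass_density must be > 0")

    @property
    def is_vacuum(self) -> bool:
        return not self.components


VACUUM = Material(id=0, name="vacuum", components=(), mass_density=0.0)


class Library:
    """A set of nuclide tables keyed by (particle type, nuclide name)."""

    def __init__(self, nuclides: list[NuclideData] | None = None):
        self._tables: dict[tuple[str, str], NuclideData] = {}
        for nuc in nuclides or []:
            self.add(nuc)

    def add(self, nuc: NuclideData) -> None:
        self._tables[(nuc.particle, nuc.name)] = nuc

    def get(self, particle: str, name: str) -> NuclideData:
        try:
            return self._tables[(particle, name)]
        except KeyError:
            raise KeyError(f"library has no {particle} table for nuclide {name!r}") from None

    def has(self, particle: str, name: str) -> bool:
        return (particle, name) in self._tables

    def __iter__(self):
        return iter(self._tables.values())

    def __len__(self) -> int:
        return len(self._tables)


# ---------------------------------------------------------------------------
# interpolation and macroscopic cross sections


def interpolate_xs(
    nuclide: NuclideData,
    reaction: str,
    energy: float,
    use_hash: bool = True,
    counter: OpCounter | None = None,
) -> float:
    """Linear-linear interpolation of a tabulated quantity at ``energy`` (eV).

    ``reaction`` is a partial name, ``"total"``, or ``"heating"`` (MeV).
    Energies must lie inside the nuclide's grid range; transport clamps or
    terminates before calling.
    """
    nodes = nuclide.grid.nodes
    if reaction == "total":
        table = nuclide.sigma_total
    elif reaction == "heating":
        table = nuclide.heating_H
    else:
        table = nuclide.partials[reaction]
    if use_hash:
        j = hash_interval(nuclide.index, nodes, energy, counter)
    else:
        j = binary_interval(nodes, energy, counter)
    e0, e1 = nodes[j], nodes[j + 1]
    f = (energy - e0) / (e1 - e0)
    return float(table[j] + f * (table[j + 1] - table[j]))


class MacroBundle:
    """Macroscopic cross sections of one material at one (particle, energy).

    Carries everything a flight and a collision need: the total macroscopic
    cross section sigma_t (1/cm), the dose response sum_i rho_i sigma_i H_i
    (MeV/cm), the B-10-only part of that response (for the separated boron
    dose component), and per-nuclide reaction breakdowns for collision
    sampling.
    """

    __slots__ = ("ptype", "material_id", "energy", "sigma_t", "response",
                 "boron_response", "entries")

    def __init__(self, ptype, material_id, energy, sigma_t, response, boron_response, entries):
        self.ptype = ptype
        self.material_id = material_id
        self.energy = energy
        self.sigma_t = sigma_t
        self.response = response
        self.boron_response = boron_response
        # entries: list of (name, rho_sigma_total, {reaction: rho_sigma}, NuclideData)
        self.entries = entries


def macro_xs(
    material: Material,
    library: Library,
    ptype: str,
    energy: float,
    use_hash: bool = True,
    counter: OpCounter | None = None,
) -> MacroBundle:
    """Evaluate sigma_t = sum_i rho_i sigma_i,total(E) and the dose response.

    The total is assembled from interpolated partials (lin-lin interpolation
    commutes with the sum rule, so this equals interpolating sigma_total).
    The photon pair channel is clamped to zero below the 1.022 MeV threshold,
    removing any sliver the interpolation leaks across the first positive
    node.  Vacuum yields sigma_t = 0.
    """
    sigma_t = 0.0
    response = 0.0
    boron_response = 0.0
    entries = []
    for name, rho in material.components:
        nuc = library.get(ptype, name)
        rsig = {}
        tot = 0.0
        for reaction in _REACTIONS[ptype]:
            if reaction not in nuc.partials:
                continue
            sig = interpolate_xs(nuc, reaction, energy, use_hash, counter)
            if reaction == "pair" and energy <= PAIR_THRESHOLD_EV:
                sig = 0.0
            rs = rho * sig
            rsig[reaction] = rs
            tot += rs
        h = interpolate_xs(nuc, "heating", energy, use_hash, counter)
        sigma_t += tot
        response += tot * h
        if name == BORON10:
            boron_response += tot * h
        entries.append((name, tot, rsig, nuc))
    return MacroBundle(ptype, material.id, energy, sigma_t, response, boron_response, entries)


# ---------------------------------------------------------------------------
# material construction


def build_material(
    mat_id: int,
    name: str,
    mass_fractions: dict[str, float],
    mass_density: float,
    boron10_ppm: float = 0.0,
    molar_masses: dict[str, float] | None = None,
) -> Material:
    """Convert mass fractions + B-10 mass ppm into number densities.

    rho_i = w_i * density * N_A / M_i, scaled by 1e-24 to atoms/(barn*cm).
    The boron addition is a trace: host densities are left unchanged
    (dilution of the host is a <=1e-4 relative effect at BNCT ppm levels).
    """
    mm = dict(MOLAR_MASS)
    if molar_masses:
        mm.update(molar_masses)
    if boron10_ppm < 0:
        raise ValueError(f"material {name!r}: boron10_ppm must be >= 0")
    total = sum(mass_fractions.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"material {name!r}: mass fractions sum to {total}, not 1")
    comps = []
    for nuc, frac in mass_fractions.items():
        if frac < 0:
            raise ValueError(f"material {name!r}: negative mass fraction for {nuc}")
        if frac == 0:
            continue
        rho = frac * mass_density * AVOGADRO / mm[nuc] * 1e-24
        comps.append((nuc, rho))
    if boron10_ppm > 0:
        rho_b = boron10_ppm * 1e-6 * mass_density * AVOGADRO / mm[BORON10] * 1e-24
        comps.append((BORON10, rho_b))
    return Material(id=mat_id, name=name, components=tuple(comps),
                    mass_density=mass_density, boron10_ppm=boron10_ppm)


# ---------------------------------------------------------------------------
# synthetic library generation

_NEUTRON_GRID = (1e-5, 20e6)
_PHOTON_GRID = (1e3, 20e6)
_EV_TO_MEV = 1e-6


def _eval_form(form: dict, name: str, reaction: str, energy: np.ndarray) -> np.ndarray:
    kind = form.get("form")
    for key, val in form.items():
        if key != "form" and isinstance(val, (int, float)) and val < 0:
            raise ValueError(f"{name}.{reaction}: parameter {key!r} must be >= 0, got {val}")
    if kind == "constant":
        return np.full_like(energy, float(form["value"]))
    if kind == "one_over_v":
        e_ref = float(form.get("E_ref", 0.0253))
        return float(form["sigma_ref"]) * np.sqrt(e_ref / energy)
    if kind == "resonance":
        e0 = float(form["E0"])
        width = float(form["width"])  # width in ln(E)
        if e0 <= 0 or width <= 0:
            raise ValueError(f"{name}.{reaction}: resonance E0 and width must be > 0")
        return float(form["peak"]) * np.exp(-0.5 * (np.log(energy / e0) / width) ** 2)
    raise ValueError(f"{name}.{reaction}: unknown functional form {kind!r}")


def _kn_mean_scattered_fraction(alpha: np.ndarray) -> np.ndarray:
    """Mean E'/E of Compton scattering at alpha = E / 511 keV (Klein-Nishina).

    Numeric quadrature over the scattering cosine, vectorized over nodes.
    """
    mu = np.linspace(-1.0, 1.0, 513)[None, :]
    a = np.asarray(alpha, dtype=np.float64)[:, None]
    eps = 1.0 / (1.0 + a * (1.0 - mu))
    dsdmu = eps * eps * (eps + 1.0 / eps - 1.0 + mu * mu)
    num = np.trapezoid(eps * dsdmu, mu[0], axis=1)
    den = np.trapezoid(dsdmu, mu[0], axis=1)
    return num / den


def make_synthetic_library(
    spec: list[dict] | None = None,
    n_nodes: int = 2000,
) -> Library:
    """Generate nuclide tables from functional parameters.

    Each entry of ``spec`` describes one table::

        {"name": "H1", "particle": "neutron", "mass_ratio_A": 0.9992,
         "reactions": {"elastic": {"form": "constant", "value": 20.4},
                       "capture": {"form": "one_over_v", "sigma_ref": 0.332}},
         "capture_gamma_mev": 2.224, "capture_q_mev": 0.0013}

    A reaction may also map to a list of form dicts, which are summed.
    Grids are log-spaced with ``n_nodes`` nodes: neutrons 1e-5 eV - 20 MeV,
    photons 1 keV - 20 MeV.  The photon pair channel is multiplied by a
    smooth threshold factor max(0, 1 - 1.022 MeV / E) so it vanishes at and
    below threshold.  Heating numbers are derived from the reaction mix:
    elastic deposits the mean recoil 2A/(A+1)^2 * E, capture deposits the
    charged-particle Q (``capture_q_mev``; the capture photon's energy is
    excluded and carried by the secondary), photoelectric deposits E, Compton
    the mean Klein-Nishina electron energy, pair E - 1.022 MeV.

    ``spec=None`` builds the default five-nuclide toy tissue set
    (:func:`toy_tissue_spec`).
    """
    if spec is None:
        spec = toy_tissue_spec()
    if not spec:
        raise ValueError("library spec names no nuclides")
    lib = Library()
    for entry in spec:
        name = entry["name"]
        particle = entry["particle"]
        a_ratio = float(entry["mass_ratio_A"])
        if a_ratio < 0:
            raise ValueError(f"{name}.mass_ratio_A: parameter must be >= 0, got {a_ratio}")
        lo, hi = _NEUTRON_GRID if particle == "neutron" else _PHOTON_GRID
        nodes = np.logspace(math.log10(lo), math.log10(hi), int(entry.get("n_nodes", n_nodes)))
        grid = EnergyGrid(nodes)
        partials: dict[str, np.ndarray] = {}
        for reaction, form in entry["reactions"].items():
            forms = form if isinstance(form, list) else [form]
            sig = np.zeros_like(nodes)
            for f in forms:
                sig = sig + _eval_form(f, name, reaction, nodes)
            if reaction == "pair":
                sig = sig * np.maximum(0.0, 1.0 - PAIR_THRESHOLD_EV / nodes)
            partials[reaction] = sig
        sigma_total = sum(partials.values())
        q_mev = float(entry.get("capture_q_mev", 0.0))
        if q_mev < 0:
            raise ValueError(f"{name}.capture_q_mev: parameter must be >= 0, got {q_mev}")
        heat = np.zeros_like(nodes)
        for reaction, sig in partials.items():
            if reaction == "elastic":
                h_r = 2.0 * a_ratio / (a_ratio + 1.0) ** 2 * nodes * _EV_TO_MEV
            elif reaction == "capture":
                h_r = np.full_like(nodes, q_mev)
            elif reaction == "photoelectric":
                h_r = nodes * _EV_TO_MEV
            elif reaction == "compton":
                h_r = nodes * _EV_TO_MEV * (1.0 - _kn_mean_scattered_fraction(nodes / 0.511e6))
            elif reaction == "pair":
                h_r = np.maximum(0.0, nodes - PAIR_THRESHOLD_EV) * _EV_TO_MEV
            else:  # pragma: no cover
                h_r = np.zeros_like(nodes)
            heat += sig * h_r
        with np.errstate(invalid="ignore"):
            heat = np.where(sigma_total > 0, heat / np.maximum(sigma_total, 1e-300), 0.0)
        lib.add(NuclideData(
            name=name, particle=particle, mass_ratio_A=a_ratio, grid=grid,
            sigma_total=sigma_total, partials=partials, heating_H=heat,
            capture_gamma_energy=float(entry.get("capture_gamma_mev", 0.0)),
        ))
    return lib


def toy_tissue_spec() -> list[dict]:
    """Default five-nuclide tissue set (H-1, C-12, N-14, O-16, B-10).

    Thermal capture magnitudes follow the familiar 1/v values (B-10 3837 b at
    0.0253 eV, H-1 0.332 b, ...); elastic channels are flat at epithermal-like
    magnitudes; O-16 carries a resonance bump to exercise that form.  Photon
    tables use constant Compton, one-over-v photoelectric, and a thresholded
    pair channel.  Magnitudes are plausible, not evaluated data.
    """
    neutron = [
        ("H1", 0.9992, 20.4, 0.332, 2.224, 0.0013, None),
        ("C12", 11.894, 4.74, 0.0035, 4.945, 0.001, None),
        ("N14", 13.883, 10.05, 1.91, 0.0, 0.62, None),
        ("O16", 15.858, 3.78, 0.00019, 4.143, 0.0004,
         {"form": "resonance", "peak": 10.0, "E0": 4.4e5, "width": 0.5}),
        ("B10", 9.927, 2.23, 3837.0, 0.478, 2.31, None),
    ]
    photon = [
        ("H1", 0.9992, 0.02, 0.30, 0.005),
        ("C12", 11.894, 1.0, 1.80, 0.20),
        ("N14", 13.883, 1.6, 2.10, 0.25),
        ("O16", 15.858, 2.4, 2.40, 0.30),
        ("B10", 9.927, 1.2, 1.50, 0.15),
    ]
    spec: list[dict] = []
    for name, a, elastic, cap_th, gamma, q, extra in neutron:
        elastic_forms: list[dict] | dict = {"form": "constant", "value": elastic}
        if extra is not None:
            elastic_forms = [elastic_forms, extra]
        spec.append({
            "name": name, "particle": "neutron", "mass_ratio_A": a,
            "reactions": {
                "elastic": elastic_forms,
                "capture": {"form": "one_over_v", "sigma_ref": cap_th},
            },
            "capture_gamma_mev": gamma, "capture_q_mev": q,
        })
    for name, a, pe, compton, pair in photon:
        spec.append({
            "name": name, "particle": "photon", "mass_ratio_A": a,
            "reactions": {
                "photoelectric": {"form": "one_over_v", "sigma_ref": pe, "E_ref": 1e3},
                "compton": {"form": "constant", "value": compton},
                "pair": {"form": "constant", "value": pair},
            },
        })
    return spec


# ---------------------------------------------------------------------------
# HDF5 container I/O


def _create_group(parent, name):
    gcpl = h5py.h5p.create(h5py.h5p.GROUP_CREATE)
    gcpl.set_obj_track_times(False)
    gid = h5py.h5g.create(parent.id, name.encode(), gcpl=gcpl)
    return h5py.Group(gid)


def write_library(library: Library, path) -> None:
    """Write the library container: /library/<particle>/<name>/{datasets}.

    Datasets: energy, sigma_total, sigma_<reaction>, heating; scalar
    attributes mass_ratio_A and capture_gamma_energy; a format-version
    attribute on /library.  Timestamp tracking is disabled so identical
    inputs produce byte-identical files.
    """
    with h5py.File(path, "w", track_order=False) as f:
        root = _create_group(f, "library")
        root.attrs["version"] = LIBRARY_FORMAT_VERSION
        by_particle: dict[str, h5py.Group] = {}
        for nuc in sorted(library, key=lambda n: (n.particle, n.name)):
            if nuc.particle not in by_particle:
                by_particle[nuc.particle] = _create_group(root, nuc.particle)
            g = _create_group(by_particle[nuc.particle], nuc.name)
            g.create_dataset("energy", data=nuc.grid.nodes, track_times=False)
            g.create_dataset("sigma_total", data=nuc.sigma_total, track_times=False)
            for reaction, sig in sorted(nuc.partials.items()):
                g.create_dataset(f"sigma_{reaction}", data=sig, track_times=False)
            g.create_dataset("heating", data=nuc.heating_H, track_times=False)
            g.attrs["mass_ratio_A"] = nuc.mass_ratio_A
            g.attrs["capture_gamma_energy"] = nuc.capture_gamma_energy


def read_library(path) -> Library:
    """Read a library container, validating structure and version."""
    lib = Library()
    with h5py.File(path, "r") as f:
        if "library" not in f:
            raise LibraryFormatError(f"{path}: no /library group")
        root = f["library"]
        version = root.attrs.get("version")
        if version != LIBRARY_FORMAT_VERSION:
            raise LibraryFormatError(
                f"{path}: missing or unsupported format version {version!r}"
            )
        for particle in root:
            for name in root[particle]:
                g = root[particle][name]
                for required in ("energy", "sigma_total", "heating"):
                    if required not in g:
                        raise LibraryFormatError(
                            f"{path}: nuclide {name!r} ({particle}) missing dataset {required!r}"
                        )
                partials = {
                    key[len("sigma_"):]: g[key][()]
                    for key in g if key.startswith("sigma_") and key != "sigma_total"
                }
                lib.add(NuclideData(
                    name=name, particle=particle,
                    mass_ratio_A=float(g.attrs["mass_ratio_A"]),
                    grid=EnergyGrid(g["energy"][()]),
                    sigma_total=g["sigma_total"][()],
                    partials=partials,
                    heating_H=g["heating"][()],
                    capture_gamma_energy=float(g.attrs["capture_gamma_energy"]),
                ))
    return lib
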