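"""Per-history neutron/photon transport on the voxel lattice.

One *history* is one source particle plus all of its secondaries (capture
photons); tally statistics are formed over histories.  The per-particle loop
is the classic surface-tracking walk:

1. sample the source state and locate the voxel (a particle starting outside
   the lattice is advanced to its entry point);
2. evaluate the material's macroscopic cross sections at the particle energy
   — unless the one-slot cache already holds them, which is the transport
   optimization: a boundary crossing into the *same* material at the *same*
   energy skips the re-evaluation entirely (it could not produce different
   numbers, so the skip changes no physics and consumes no random numbers);
3. sample an exponential free-flight distance and compare with the distance
   to the voxel surface; score the traversed segment with the track-length
   estimator either way;
4. collide or cross, until escape, absorption, energy cutoff, or the
   collision cap.

The collision kernel is deliberately minimal but exact within its scope:
neutrons undergo isotropic-in-CM elastic scattering off stationary targets
(E'/E in [alpha, 1], alpha = ((A-1)/(A+1))^2) and radiative capture (which
may emit one isotropic capture photon, transported in the same history);
photons undergo photoelectric absorption, Klein-Nishina Compton scattering,
and pair production above 1.022 MeV (terminating without annihilation
quanta).  Electrons are never banked: charged particles deposit locally.

Randomness: history h of a run with root seed s draws from the independent
substream SeedSequence(entropy=s, spawn_key=(h,)), so the run is a pure map
over histories — identical output for any worker count or batching.
"""

from __future__ import annotations

import math

import numpy as np

from .energy_search import OpCounter
from .lattice import OUTSIDE, Phantom, distance_to_boundary, locate_voxel, ray_box_entry
from .nuclear_data import Library, MacroBundle, PAIR_THRESHOLD_EV, macro_xs
from .source import SourceSpec, sample_source
from .tally import TallyGrid

__all__ = [
    "ParticleState",
    "XsCache",
    "Engine",
    "sample_path_length",
    "collide_neutron",
    "collide_photon",
    "sample_klein_nishina",
    "rotate_direction",
]

ELECTRON_REST_EV = 0.511e6


class ParticleState:
    """The transported entity: type, position (cm), unit direction, E (eV)."""

    __slots__ = ("ptype", "position", "direction", "energy", "voxel", "alive",
                 "collision_count")

    def __init__(self, ptype, position, direction, energy):
        self.ptype = ptype
        self.position = list(position)
        self.direction = list(direction)
        self.energy = float(energy)
        self.voxel = None
        self.alive = True
        self.collision_count = 0


class XsCache:
    """One-slot macroscopic cross-section cache.

    Valid only while the particle's (type, material, energy) all match the
    stored key; a same-material boundary crossing leaves it valid, any
    collision (energy change) or material change invalidates it.
    """

    __slots__ = ("key", "bundle", "hits", "misses")

    def __init__(self):
        self.key = None
        self.bundle = None
        self.hits = 0
        self.misses = 0


def sample_path_length(sigma_t: float, rng) -> float:
    """Exponential free flight: d = -ln(xi)/sigma_t; vacuum -> infinity."""
    if sigma_t < 0:
        raise ValueError("sigma_t must be nonnegative")
    if sigma_t == 0.0:
        return math.inf
    return -math.log(1.0 - rng.random()) / sigma_t


def rotate_direction(direction, mu: float, phi: float) -> list[float]:
    """Rotate a unit vector by polar cosine ``mu`` and azimuth ``phi``."""
    u, v, w = direction
    s = math.sqrt(max(0.0, 1.0 - mu * mu))
    cp, sp = math.cos(phi), math.sin(phi)
    denom = math.sqrt(max(0.0, 1.0 - w * w))
    if denom > 1e-10:
        nu = mu * u + s * (u * w * cp - v * sp) / denom
        nv = mu * v + s * (v * w * cp + u * sp) / denom
        nw = mu * w - s * denom * cp
    else:
        sign = 1.0 if w >= 0 else -1.0
        nu = s * cp
        nv = sign * s * sp
        nw = sign * mu
    norm = math.sqrt(nu * nu + nv * nv + nw * nw)
    return [nu / norm, nv / norm, nw / norm]


def _choose(entries_total: float, pairs, rng):
    """Pick from (weight, payload) pairs with probability weight/total."""
    xi = rng.random() * entries_total
    acc = 0.0
    payload = pairs[-1][1]
    for w, item in pairs:
        acc += w
        if xi < acc:
            payload = item
            break
    return payload


def collide_neutron(state: ParticleState, bundle: MacroBundle, rng):
    """Neutron collision: elastic scatter or radiative capture.

    Nuclide chosen proportional to rho*sigma_total, reaction proportional to
    the nuclide's partials.  Elastic scattering is isotropic in the
    center-of-mass frame off a stationary target of mass ratio A.  Capture
    terminates the history branch and may return one isotropic secondary
    photon carrying the nuclide's capture-gamma energy.
    """
    if not bundle.entries or bundle.sigma_t <= 0.0:
        raise RuntimeError("collision sampled in vacuum or zero-cross-section material")
    name, rst, rsig, nuc = _choose(
        bundle.sigma_t, [(e[1], e) for e in bundle.entries], rng)
    reaction = _choose(rst, [(w, r) for r, w in rsig.items()], rng)
    state.collision_count += 1
    if reaction == "elastic":
        a = nuc.mass_ratio_A
        mu_cm = 2.0 * rng.random() - 1.0
        q = 1.0 + a * a + 2.0 * a * mu_cm
        e_new = state.energy * q / ((a + 1.0) * (a + 1.0))
        mu_lab = (1.0 + a * mu_cm) / math.sqrt(q) if q > 0 else -1.0
        phi = 2.0 * math.pi * rng.random()
        state.direction = rotate_direction(state.direction, mu_lab, phi)
        state.energy = e_new
        return None
    # capture
    state.alive = False
    if nuc.capture_gamma_energy > 0.0:
        mu = 2.0 * rng.random() - 1.0
        phi = 2.0 * math.pi * rng.random()
        s = math.sqrt(max(0.0, 1.0 - mu * mu))
        sec = ParticleState(
            ptype="photon",
            position=list(state.position),
            direction=[s * math.cos(phi), s * math.sin(phi), mu],
            energy=nuc.capture_gamma_energy * 1e6,
        )
        return sec
    return None


def sample_klein_nishina(alpha: float, rng) -> tuple[float, float]:
    """Sample the Compton scattered-energy fraction and cosine.

    Rejection on the Klein-Nishina differential cross section: the scoring
    function g(mu) = eps^2 (eps + 1/eps - 1 + mu^2) with
    eps = 1/(1 + alpha(1 - mu)) is bounded by 2 for every alpha > 0, so a
    uniform proposal in mu with envelope 2 is exact.
    """
    while True:
        mu = 2.0 * rng.random() - 1.0
        eps = 1.0 / (1.0 + alpha * (1.0 - mu))
        g = eps * eps * (eps + 1.0 / eps - 1.0 + mu * mu)
        if 2.0 * rng.random() <= g:
            return eps, mu


def collide_photon(state: ParticleState, bundle: MacroBundle, rng) -> None:
    """Photon collision: photoelectric, Compton, or pair production."""
    if not bundle.entries or bundle.sigma_t <= 0.0:
        raise RuntimeError("collision sampled in vacuum or zero-cross-section material")
    name, rst, rsig, nuc = _choose(
        bundle.sigma_t, [(e[1], e) for e in bundle.entries], rng)
    reaction = _choose(rst, [(w, r) for r, w in rsig.items()], rng)
    state.collision_count += 1
    if reaction == "compton":
        alpha = state.energy / ELECTRON_REST_EV
        eps, mu = sample_klein_nishina(alpha, rng)
        phi = 2.0 * math.pi * rng.random()
        state.direction = rotate_direction(state.direction, mu, phi)
        state.energy = eps * state.energy
        return
    if reaction == "pair" and state.energy <= PAIR_THRESHOLD_EV:  # pragma: no cover
        raise RuntimeError("pair production sampled below threshold")
    # photoelectric or pair: history branch ends, deposition was in H(E)
    state.alive = False


class Engine:
    """Transport engine binding phantom, library, source and options."""

    def __init__(
        self,
        phantom: Phantom,
        library: Library,
        source: SourceSpec,
        tally_mode: str = "fragment",
        use_hash: bool = True,
        use_cache: bool = True,
        neutron_cutoff_ev: float = 1e-5,
        photon_cutoff_ev: float = 1e3,
        collision_cap: int = 100_000,
        count_searches: bool = False,
    ):
        self.phantom = phantom
        self.lattice = phantom.lattice
        self.materials = phantom.materials
        self.library = library
        self.source = source
        self.tally_mode = tally_mode
        self.use_hash = use_hash
        self.use_cache = use_cache
        self.neutron_cutoff_ev = neutron_cutoff_ev
        self.photon_cutoff_ev = photon_cutoff_ev
        self.collision_cap = collision_cap
        self.search_counter = OpCounter() if count_searches else None
        self.cache = XsCache()
        self.counters = {"collisions": 0, "segments": 0, "escapes": 0,
                         "cap_hits": 0, "cache_hits": 0, "cache_misses": 0}
        self._validate()

    def _validate(self) -> None:
        """Fail at initialization, never mid-run, on unknown nuclides."""
        source_types = {t for t, _ in self.source.particle_mix}
        needs_photon = "photon" in source_types
        used = set()
        for mid in np.unique(self.lattice.material_id):
            if int(mid) not in self.materials:
                raise ValueError(f"lattice references undefined material id {int(mid)}")
            used.add(int(mid))
        for mid in used:
            mat = self.materials[mid]
            for name, _ in mat.components:
                for ptype in source_types:
                    if not self.library.has(ptype, name):
                        raise ValueError(
                            f"library has no {ptype} table for nuclide {name!r} "
                            f"used by material {mat.name!r}")
                if (self.library.has("neutron", name)
                        and self.library.get("neutron", name).capture_gamma_energy > 0):
                    needs_photon = True
        if needs_photon:
            for mid in used:
                for name, _ in self.materials[mid].components:
                    if not self.library.has("photon", name):
                        raise ValueError(
                            f"capture photons are emitted but material nuclide {name!r} "
                            f"has no photon table")

    def make_tally(self) -> TallyGrid:
        return TallyGrid(self.lattice.dims, self.lattice.voxel_volume, self.tally_mode)

    # -- macro-XS lookup with the skip cache ------------------------------

    def _bundle(self, ptype: str, material, energy: float) -> MacroBundle:
        cache = self.cache
        if self.use_cache:
            key = (ptype, material.id, energy)
            if cache.key == key:
                cache.hits += 1
                self.counters["cache_hits"] += 1
                return cache.bundle
            cache.misses += 1
            self.counters["cache_misses"] += 1
            bundle = macro_xs(material, self.library, ptype, energy,
                              self.use_hash, self.search_counter)
            cache.key = key
            cache.bundle = bundle
            return bundle
        return macro_xs(material, self.library, ptype, energy,
                        self.use_hash, self.search_counter)

    # -- the per-history loop ---------------------------------------------

    def history_rng(self, seed: int, h: int) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(
            np.random.SeedSequence(entropy=seed, spawn_key=(h,))))

    def simulate_history(self, rng, tally: TallyGrid) -> None:
        """Run one full history (source particle + secondaries) into ``tally``."""
        stack = [sample_source(self.source, rng)]
        while stack:
            self._transport(stack.pop(), rng, stack, tally)
        tally.end_history()

    def _transport(self, p: ParticleState, rng, stack, tally: TallyGrid) -> None:
        lat = self.lattice
        counters = self.counters
        vox = locate_voxel(lat, p.position)
        if vox is OUTSIDE:
            t_entry = ray_box_entry(lat, p.position, p.direction)
            if t_entry is None:
                counters["escapes"] += 1
                return
            nudge = t_entry + 1e-9 * min(lat.spacing)
            for ax in range(3):
                p.position[ax] += nudge * p.direction[ax]
            vox = locate_voxel(lat, p.position)
            if vox is OUTSIDE:
                counters["escapes"] += 1
                return
        p.voxel = vox
        cutoff = self.neutron_cutoff_ev if p.ptype == "neutron" else self.photon_cutoff_ev
        if p.energy < cutoff:
            return
        mat_ids = lat.material_id
        _, ny, nz = lat.dims
        while p.alive:
            material = self.materials[int(mat_ids[vox])]
            if material.is_vacuum:
                bundle = None
                d_coll = math.inf
            else:
                bundle = self._bundle(p.ptype, material, p.energy)
                d_coll = sample_path_length(bundle.sigma_t, rng)
            d_bound, nxt = distance_to_boundary(lat, p.position, p.direction, vox)
            if d_bound < 0.0:
                d_bound = 0.0
            if d_coll < d_bound:
                if bundle is not None:
                    i, j, k = vox
                    tally.score_segment((i * ny + j) * nz + k, d_coll, bundle, material)
                    counters["segments"] += 1
                for ax in range(3):
                    p.position[ax] += d_coll * p.direction[ax]
                if p.ptype == "neutron":
                    sec = collide_neutron(p, bundle, rng)
                    if sec is not None:
                        stack.append(sec)
                else:
                    collide_photon(p, bundle, rng)
                counters["collisions"] += 1
                if p.alive and p.energy < cutoff:
                    p.alive = False
                if p.alive and p.collision_count >= self.collision_cap:
                    counters["cap_hits"] += 1
                    p.alive = False
            else:
                if bundle is not None and d_bound > 0.0:
                    i, j, k = vox
                    tally.score_segment((i * ny + j) * nz + k, d_bound, bundle, material)
                    counters["segments"] += 1
                for ax in range(3):
                    p.position[ax] += d_bound * p.direction[ax]
                if nxt is OUTSIDE:
                    counters["escapes"] += 1
                    return
                vox = nxt
                p.voxel = nxt

    # -- whole runs --------------------------------------------------------

    def run(
        self,
        n_histories: int,
        seed: int,
        workers: int = 1,
        block_size: int = 1024,
    ) -> TallyGrid:
        """Simulate ``n_histories`` histories; returns the merged tally.

        Histories are processed in fixed blocks of ``block_size`` and block
        results are reduced in block order, so the accumulated sums are
        bit-identical for any worker count.  (``block_size`` itself is part
        of the reduction order: changing it regroups floating-point
        additions, which is why it is a fixed default rather than a tuning
        knob exposed through the run configuration.)
        """
        if n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        blocks = [(b, min(b + block_size, n_histories))
                  for b in range(0, n_histories, block_size)]
        total = self.make_tally()
        for key in self.counters:
            self.counters[key] = 0
        if workers <= 1 or len(blocks) == 1:
            for b0, b1 in blocks:
                block = self._run_block(seed, b0, b1)
                total.merge(block)
        else:
            import multiprocessing as mp

            ctx = mp.get_context("fork")
            with ctx.Pool(workers, initializer=_set_worker_engine,
                          initargs=(self,)) as pool:
                for block, counters in pool.imap(
                        _run_worker_block, [(seed, b0, b1) for b0, b1 in blocks]):
                    total.merge(block)
                    for key, val in counters.items():
                        self.counters[key] += val
        return total

    def _run_block(self, seed: int, b0: int, b1: int) -> TallyGrid:
        block = self.make_tally()
        for h in range(b0, b1):
            self.simulate_history(self.history_rng(seed, h), block)
        return block


_WORKER_ENGINE: Engine | None = None


def _set_worker_engine(engine: Engine) -> None:
    global _WORKER_ENGINE
    _WORKER_ENGINE = engine
    for key in engine.counters:
        engine.counters[key] = 0


def _run_worker_block(args):
    seed, b0, b1 = args
    eng = _WORKER_ENGINE
    for key in eng.counters:
        eng.counters[key] = 0
    block = eng._run_block(seed, b0, b1)
    return block, dict(eng.counters)
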