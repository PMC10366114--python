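"""Track-length dose tallies and their statistics.

Every flight segment of length l (cm) through a voxel contributes a
per-source-particle flux phi = l / V and a dose fragment

    t = phi * sum_i rho_i sigma_i(E) H_i(E) / mass_density   [MeV/g]

to the voxel it crosses.  Neutron segments score into the *neutron*
component (all nuclides, boron included) and additionally score the
B-10-only part of the response into the separated *boron* component;
photon segments score into *photon*.

Two accumulation modes produce identical means but different error
estimates.  With per-history tallies t_i over N histories,

    mean  = (sum_i t_i) / N
    error = sqrt(((sum_i t_i^2)/N - mean^2) / (N - 1))

*history* mode is the exact estimator: fragments of one history landing in
the same voxel are summed first, so the squared term is (t_1 + t_2)^2.
*fragment* mode commits t and t^2 at scoring time, giving t_1^2 + t_2^2 —
cheaper (no per-history voxel map) and identical in the mean, but the
reported error is underestimated whenever a history revisits a voxel,
since t_1^2 + t_2^2 < (t_1 + t_2)^2 for positive fragments.
"""

from __future__ import annotations

import numpy as np

from .nuclear_data import MacroBundle, Material

__all__ = ["COMPONENTS", "TallyGrid", "DoseResult"]

COMPONENTS = ("boron", "neutron", "photon")
_CIDX = {c: i for i, c in enumerate(COMPONENTS)}


class DoseResult:
    """Finalized per-voxel dose means and relative errors.

    ``mean`` and ``rel_error_pct`` have shape (3, nx, ny, nz), indexed by
    component order ("boron", "neutron", "photon").  Means are MeV/g per
    source particle; relative errors are percent (0 where the mean is 0).
    """

    def __init__(self, mean: np.ndarray, rel_error_pct: np.ndarray, n_histories: int):
        self.mean = mean
        self.rel_error_pct = rel_error_pct
        self.n_histories = n_histories

    def component(self, name: str) -> np.ndarray:
        return self.mean[_CIDX[name]]

    def component_error(self, name: str) -> np.ndarray:
        return self.rel_error_pct[_CIDX[name]]


class TallyGrid:
    """Per-voxel, per-component accumulators sum(t) and sum(t^2)."""

    def __init__(self, dims: tuple[int, int, int], voxel_volume: float,
                 mode: str = "fragment"):
        if mode not in ("fragment", "history"):
            raise ValueError(f"unknown tally mode {mode!r}")
        self.dims = tuple(dims)
        self.voxel_volume = float(voxel_volume)
        self.mode = mode
        nvox = dims[0] * dims[1] * dims[2]
        self.sum_t = np.zeros((3, nvox))
        self.sum_t2 = np.zeros((3, nvox))
        self.n_histories = 0
        self._scratch: dict[tuple[int, int], float] = {}

    def score_segment(
        self,
        voxel_flat: int,
        length: float,
        bundle: MacroBundle,
        material: Material,
    ) -> None:
        """Score one flight segment of ``length`` cm through one voxel."""
        if length < 0:
            raise ValueError("segment length must be nonnegative")
        if length == 0.0 or material.is_vacuum or bundle.response == 0.0:
            return
        phi = length / self.voxel_volume
        t = phi * bundle.response / material.mass_density
        if bundle.ptype == "photon":
            self._add(2, voxel_flat, t)
        else:
            self._add(1, voxel_flat, t)
            if bundle.boron_response > 0.0:
                tb = phi * bundle.boron_response / material.mass_density
                self._add(0, voxel_flat, tb)

    def _add(self, comp: int, voxel_flat: int, t: float) -> None:
        if self.mode == "fragment":
            self.sum_t[comp, voxel_flat] += t
            self.sum_t2[comp, voxel_flat] += t * t
        else:
            key = (comp, voxel_flat)
            self._scratch[key] = self._scratch.get(key, 0.0) + t

    def end_history(self) -> None:
        """Close out one history (one source particle plus all secondaries).

        History mode commits each voxel's summed fragments and their square;
        fragment mode already committed at scoring time.  The history count
        advances in both modes.
        """
        if self.mode == "history" and self._scratch:
            for (comp, vox), t in self._scratch.items():
                self.sum_t[comp, vox] += t
                self.sum_t2[comp, vox] += t * t
            self._scratch.clear()
        self.n_histories += 1

    def merge(self, other: "TallyGrid") -> None:
        """Accumulate another (completed) tally block into this one."""
        if other._scratch:
            raise ValueError("cannot merge a tally with an open history")
        self.sum_t += other.sum_t
        self.sum_t2 += other.sum_t2
        self.n_histories += other.n_histories

    def finalize(self) -> DoseResult:
        """Mean and relative error per voxel and component.

        mean = sum_t / N; error = sqrt((sum_t2/N - mean^2)/(N-1));
        relative error (%) = 100 * error / mean, 0 where the mean is 0.
        Requires N >= 2.
        """
        n = self.n_histories
        if n < 2:
            raise ValueError(f"error estimate undefined for N={n} < 2 histories")
        mean = self.sum_t / n
        var = (self.sum_t2 / n - mean * mean) / (n - 1)
        np.clip(var, 0.0, None, out=var)  # guard round-off at zero variance
        err = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mean > 0, 100.0 * err / np.where(mean > 0, mean, 1.0), 0.0)
        shape = (3, *self.dims)
        return DoseResult(mean.reshape(shape), rel.reshape(shape), n)
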