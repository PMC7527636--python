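"""Cell-model bundle: morphology + passive membrane + channel complement.

``CellModel`` owns the discretized geometry (computed once at reference
passive parameters so that re-fitting passive values rescales the electrical
system without re-gridding) and knows how to materialize the channel list for
the simulator: I_h distributed by ``H_dist``, region-specific Na_T, and any
generic spiking channels with per-region densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import (
    ChannelSpec,
    IhParams,
    NaTParams,
    builtin_spiking_config,
    ih_channel_spec,
    nat_channel_spec,
)
from .morphology import (
    CompartmentalModel,
    Morphology,
    discretize,
    distribute_conductance,
    select_by_hdist,
)
from .simulator import PassiveParams, Simulator, density_by_region

__all__ = ["CellModel"]


@dataclass
class CellModel:
    """A cell's morphology with its fitted biophysical parameter sets.

    ``spiking`` maps generic channel name -> {'soma': d, 'dend': d, 'axon': d}
    densities in pS/um^2; names resolve against ``channel_config`` (defaults
    to the bundled spiking set).
    """

    morphology: Morphology
    passive: PassiveParams
    ih: IhParams | None = None
    nat: NaTParams | None = None
    spiking: dict[str, dict[str, float]] | None = None
    fraction: float = 0.1
    f: float = 100.0
    channel_config: dict[str, ChannelSpec] | None = None
    _geometry: CompartmentalModel | None = field(default=None, repr=False)

    @property
    def geometry(self) -> CompartmentalModel:
        if self._geometry is None:
            self._geometry = discretize(
                self.morphology, self.fraction, self.f, self.passive.Ra, self.passive.Cm
            )
        return self._geometry

    def ih_density(self) -> np.ndarray:
        """Per-compartment I_h density (pS/um^2) for the current H_dist."""
        geom = self.geometry
        dens = np.zeros(geom.n)
        if self.ih is not None and self.ih.gh_total_nS > 0:
            sel = select_by_hdist(geom, self.ih.h_dist)
            dens[sel] = distribute_conductance(geom, self.ih.gh_total_nS, sel)
        return dens

    def channel_list(self) -> list[tuple[ChannelSpec, np.ndarray]]:
        geom = self.geometry
        channels: list[tuple[ChannelSpec, np.ndarray]] = []
        if self.ih is not None and self.ih.gh_total_nS > 0:
            channels.append((ih_channel_spec(self.ih), self.ih_density()))
        if self.nat is not None:
            for region, dens, shift in (
                ("soma", self.nat.g_soma, self.nat.v_shift_soma),
                ("dend", self.nat.g_dend, self.nat.v_shift_dend),
                ("axon", self.nat.g_axon, self.nat.v_shift_axon),
            ):
                if dens > 0:
                    arr = density_by_region(geom, **{region: dens})
                    channels.append(
                        (nat_channel_spec(region, shift, self.nat.e_na), arr)
                    )
        if self.spiking:
            config = self.channel_config or builtin_spiking_config()
            for name, regions in self.spiking.items():
                arr = density_by_region(geom, **regions)
                if np.any(arr > 0):
                    channels.append((config[name], arr))
        return channels

    def simulator(self, **kw) -> Simulator:
        return Simulator(self.geometry, self.passive, self.channel_list(), **kw)

    def replace(self, **kw) -> "CellModel":
        """Copy with updated parameter sets; geometry is re-used when only
        electrical parameters change."""
        new = CellModel(
            morphology=self.morphology,
            passive=kw.get("passive", self.passive),
            ih=kw.get("ih", self.ih),
            nat=kw.get("nat", self.nat),
            spiking=kw.get("spiking", self.spiking),
            fraction=self.fraction,
            f=self.f,
            channel_config=self.channel_config,
        )
        new._geometry = self._geometry
        return new
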