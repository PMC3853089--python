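"""End-to-end convenience wrappers used by the CLI and the acceptance script."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hydration_stats as hs
from .interface_graph import (
    BurialMap,
    ContactGraph,
    EXPOSURE_THRESHOLD,
    TripartiteInterface,
    WATER_DIAMETER,
    build_contact_graph,
    burial_levels,
    extract_interface,
    prune_exposed_waters,
)
from .structure_io import SasaMap, Structure, assign_radii, compute_sasa


@dataclass
class PipelineConfig:
    radii_table: str = "protor"
    probe_radius: float = 1.4
    sasa_points: int = 960
    sasa_cut: float = EXPOSURE_THRESHOLD
    water_diameter: float = WATER_DIAMETER


@dataclass
class InterfaceResult:
    """Everything the interface pipeline produces for one chain pair."""

    structure: Structure  # pruned, radii assigned
    graph: ContactGraph
    sasa: SasaMap
    burial: BurialMap
    interface: TripartiteInterface
    config: PipelineConfig = field(repr=False, default_factory=PipelineConfig)

    def summary(self, with_delta_sasa: bool = True) -> hs.HydrationSummary:
        dsasa = None
        if with_delta_sasa:
            dsasa = hs.delta_sasa(
                self.structure,
                self.interface.chain1,
                self.interface.chain2,
                probe=self.config.probe_radius,
                n_points=self.config.sasa_points,
            )
        return hs.summarize(self.interface, self.burial, delta_sasa_value=dsasa)


def run_interface_pipeline(
    s: Structure,
    chain1: str,
    chain2: str,
    config: PipelineConfig | None = None,
) -> InterfaceResult:
    """Prune bulk waters, build the contact graph, extract the interface, grade burial.

    ``s`` should be a freshly read structure; radii are (re)assigned from
    ``config.radii_table`` before any SASA computation.
    """
    config = config or PipelineConfig()
    s = assign_radii(s, config.radii_table)
    s.require_chain(chain1)
    s.require_chain(chain2)
    pruned = prune_exposed_waters(
        s,
        sasa_threshold=config.sasa_cut,
        probe=config.probe_radius,
        n_points=config.sasa_points,
    )
    graph = build_contact_graph(pruned, water_diameter=config.water_diameter)
    sasa = compute_sasa(pruned, probe=config.probe_radius, n_points=config.sasa_points)
    burial = burial_levels(graph, sasa, threshold=config.sasa_cut)
    interface = extract_interface(graph, pruned, chain1, chain2)
    return InterfaceResult(
        structure=pruned,
        graph=graph,
        sasa=sasa,
        burial=burial,
        interface=interface,
        config=config,
    )


def per_atom_table(result: InterfaceResult):
    """Rows (one per interface atom) for the TSV reports."""
    import pandas as pd

    s = result.structure
    iface = result.interface
    counts = hs.water_contact_counts(iface) if iface.n_atoms else None
    y_of = (
        {int(i): int(c) for i, c in zip(counts.atom_indices, counts.counts)}
        if counts is not None
        else {}
    )
    side_of = {}
    for i in iface.side1_atoms:
        side_of[i] = iface.chain1
    for i in iface.side2_atoms:
        side_of[i] = iface.chain2
    for i in iface.water_atoms:
        side_of[i] = "water"
    rows = []
    for i in sorted(iface.atoms):
        rows.append(
            {
                "serial": int(s.serial[i]),
                "label": s.atom_label(i),
                "side": side_of[i],
                "burial_level": int(result.burial.levels[i]),
                "sasa": float(result.sasa.values[i]),
                "water_contacts": y_of.get(i, np.nan if s.is_water[i] else 0),
            }
        )
    return pd.DataFrame(rows)
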