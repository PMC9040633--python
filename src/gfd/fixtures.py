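"""Packaged fixtures: the acetogen core network and the gas-condition table.

The core network is a hand-transcribed 70-reaction / 62-metabolite
representation of *C. autoethanogenum* core metabolism: Wood-Ljungdahl
pathway, CO dehydrogenase, the two electron-bifurcating hydrogenases
(NADP- and NAD-linked), Nfn transhydrogenase, Rnf + ATP synthase
chemiosmosis, ATP maintenance, acetate (PTA/ACK), ethanol (ALCDx/ALCDy/
ACALDy/ACAFDOR) and lactate branches, the 2,3-butanediol branch
(PFOR, ACLS, ACLDC, BTDDx), gluconeogenesis down to hexose phosphates
(FBP, FRUK, FRUpts), a partial reductive TCA arm, amino-acid drains
(GLUD, HSDH and relatives), a lumped biomass equation (38 C per unit,
growth-associated ATP 90 mmol/gCDW) and exchanges for CO, CO2, H2, water,
protons, ammonium, acetate, ethanol, lactate, 2,3-BDO, THF and biomass.

Every internal reaction is elementally balanced (C/H/O/N/P/S plus the
ferredoxin pseudo-element), and the fixture passes both network-consistency
tests with exact zeros.  The gas table reproduces the printed validation
data sets; two rows printed on a 1000x scale are normalized at load time.
"""

from __future__ import annotations

from importlib import resources

from .model import GasConditionTable, MetabolicNetwork, load_network_tsv, read_gas_table

__all__ = ["core_network_fixture", "gas_table_fixture"]

_cached_network: MetabolicNetwork | None = None


def _data_path(name: str):
    return resources.files("gfd").joinpath("data", name)


def core_network_fixture() -> MetabolicNetwork:
    """Return a fresh copy of the packaged acetogen core network."""
    global _cached_network
    if _cached_network is None:
        with resources.as_file(_data_path("core_network.tsv")) as p:
            _cached_network = load_network_tsv(p)
    return _cached_network.copy()


def gas_table_fixture() -> GasConditionTable:
    """Return the 8-row gas-fermentation validation table (mmol/gCDW/h)."""
    with resources.as_file(_data_path("gas_conditions.csv")) as p:
        return read_gas_table(p)
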