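"""Packaged volvocine fixture: chronogram, trait matrix, calibration table.

The fixture transcribes the study system at genus/species resolution
(~28 tips): a rooted chronogram whose node ages are the CIR-clock posterior
means reported for the key volvocine divergences, a discrete trait matrix
covering cellularity, body plan, inversion, the twelve developmental steps
of Kirk's program, and seven sexual traits, and the 14-row Archaeplastida
fossil calibration table.  Every coded state traces to a published statement
about the study system (see the provenance table); codings without such a
main-text statement are marked missing ("?").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_calibrations, write_calibrations, write_newick, write_traits
from .tables import CalibrationTable, TraitMatrix
from .tree import MY, RootedTree

__all__ = ["VolvocineFixture", "build_volvocine_fixture", "volvocine_tree",
           "volvocine_traits", "archaeplastida_calibrations"]


# ----------------------------------------------------------------------
# Topology + CIR mean node ages (My).  Named internal nodes carry ages
# reported in the study; unnamed interior ages are interpolated to respect
# parent > child ordering.
# ----------------------------------------------------------------------
_TREE = ("tgv_crown", 298.0, [
    ("tet_vitreo_split", 267.0, [
        "Vitreochlamys_ordinata",
        ("tet_crown", 89.0, [
            "Basichlamys_sacculifera",
            ("tsocialis_split", 51.0, [
                "Tetrabaena_socialis_NIES571",
                "Tetrabaena_socialis_NIES691",
            ]),
        ]),
    ]),
    ("gv_chlamy_split", 274.0, [
        "Chlamydomonas_reinhardtii",
        ("gv_crown", 247.0, [
            ("gonium_astrephomene_split", 220.0, [
                "Gonium_pectorale", "Astrephomene_gubernaculifera",
            ]),
            ("volvocaceae_crown", 228.0, [
                ("section_volvox_crown", 95.0, [
                    "Volvox_rousseletii", "Volvox_barberi",
                ]),
                ("pvc_ye_split", 210.0, [
                    ("pvc_crown", 180.0, [
                        "Pandorina_morum",
                        ("volvulina_split", 150.0, [
                            "Volvulina_steinii",
                            ("platydorina_colemanosphaera_split", 80.0, [
                                "Platydorina_caudata",
                                "Colemanosphaera_charkowiensis",
                            ]),
                        ]),
                    ]),
                    ("yam_evp_split", 190.0, [
                        "Yamagishiella_unicocca",
                        ("evp_crown", 152.0, [
                            "Eudorina_elegans",
                            ("evp_inner", 140.0, [
                                ("thompsonii_clade", 134.0, [
                                    "Pleodorina_thompsonii",
                                    ("eudorina_grade_1", 131.0, [
                                        "Eudorina_elegans_UTEX1193",
                                        ("eudorina_grade_2", 130.0, [
                                            "Eudorina_cylindrica",
                                            ("aureus_carteri_mrca", 129.0, [
                                                "Volvox_aureus",
                                                ("japonica_clade", 125.0, [
                                                    "Pleodorina_japonica",
                                                    ("africanus_carteri_mrca", 118.0, [
                                                        "Volvox_africanus",
                                                        ("obversus_carteri_split", 98.0, [
                                                            "Volvox_obversus",
                                                            "Volvox_carteri",
                                                        ]),
                                                    ]),
                                                ]),
                                            ]),
                                        ]),
                                    ]),
                                ]),
                                ("gigas_side", 120.0, [
                                    "Eudorina_unicocca",
                                    ("starrii_gigas_clade", 110.0, [
                                        "Pleodorina_starrii",
                                        ("eudorina_grade_3", 90.0, [
                                            "Eudorina_elegans_NIES456",
                                            ("gigas_powersii_split", 46.0, [
                                                "Volvox_gigas", "Volvox_powersii",
                                            ]),
                                        ]),
                                    ]),
                                ]),
                            ]),
                        ]),
                    ]),
                ]),
            ]),
        ]),
    ]),
])

# 95% HPD intervals (lower, upper) reported for the anchored nodes
NODE_HPD = {
    "tgv_crown": (237.0, 349.0),
    "tet_vitreo_split": (206.0, 316.0),
    "gv_chlamy_split": (214.0, 323.0),
    "tet_crown": (49.0, 126.0),
    "gv_crown": (190.0, 297.0),
    "volvocaceae_crown": (175.0, 279.0),
    "gonium_astrephomene_split": (170.0, 274.0),
    "tsocialis_split": (25.0, 82.0),
    "section_volvox_crown": (57.0, 136.0),
    "evp_crown": (117.0, 196.0),
    "gigas_powersii_split": (28.0, 68.0),
}


def volvocine_tree() -> tuple[RootedTree, dict[str, int]]:
    """The fixture chronogram and a name -> node id map for its named nodes."""
    parent: list[int] = []
    children: list[list[int]] = []
    labels: list[str | None] = []
    ages: list[float] = []
    named: dict[str, int] = {}

    def emit(node, p: int) -> int:
        i = len(parent)
        parent.append(p)
        children.append([])
        if p >= 0:
            children[p].append(i)
        if isinstance(node, str):
            labels.append(node)
            ages.append(0.0)
        else:
            name, age, kids = node
            labels.append(None)
            ages.append(age)
            named[name] = i
            for kid in kids:
                emit(kid, i)
        return i

    emit(_TREE, -1)
    ages_arr = np.array(ages)
    lengths = np.zeros(len(parent))
    for v in range(len(parent)):
        if parent[v] >= 0:
            lengths[v] = ages_arr[parent[v]] - ages_arr[v]
    tree = RootedTree(parent, children, labels, lengths, length_kind=MY, ages=ages_arr)
    return tree, named


# ----------------------------------------------------------------------
# Trait codings (main-text statements only; "?" = not stated there)
# ----------------------------------------------------------------------
_CHARACTERS = (
    ["cellularity", "spheroid", "inversion"]
    + [f"kirk_step_{i}" for i in range(1, 13)]
    + ["gametes3", "gametes2", "somatic_cells", "germ_cells",
       "meiotic_hatching", "mating_system", "internal_fert",
       "extrafertile_females", "dwarf_males"]
)

_STATE_SPACES = {
    "cellularity": ["uni", "multi"],
    "spheroid": ["0", "1"],
    "inversion": ["none", "partial", "complete"],
    "gametes3": ["iso", "aniso", "oog"],
    "gametes2": ["iso", "aniso"],
    "somatic_cells": ["0", "1"],
    "germ_cells": ["0", "1"],
    "meiotic_hatching": ["full", "reduced"],
    "mating_system": ["dioecy", "monoecy"],
    "internal_fert": ["0", "1"],
    "extrafertile_females": ["0", "1"],
    "dwarf_males": ["0", "1"],
    **{f"kirk_step_{i}": ["0", "1"] for i in range(1, 13)},
}

_SEXUAL = ["gametes3", "gametes2", "meiotic_hatching", "mating_system",
           "internal_fert", "extrafertile_females", "dwarf_males"]


def _tip(cellularity="uni", spheroid="0", inversion="none", kirk=(),
         g3="iso", soma="0", germ="0", hatch="full", mating="dioecy",
         internal="0", extraf="0", dwarf="0", unknown_sexual=False,
         hatch_unknown=False):
    row = {
        "cellularity": cellularity,
        "spheroid": spheroid,
        "inversion": inversion,
        "gametes3": g3,
        "somatic_cells": soma,
        "germ_cells": germ,
        "meiotic_hatching": hatch,
        "mating_system": mating,
        "internal_fert": internal,
        "extrafertile_females": extraf,
        "dwarf_males": dwarf,
    }
    for i in range(1, 13):
        row[f"kirk_step_{i}"] = "1" if i in kirk else "0"
    row["kirk_step_9"] = soma
    row["kirk_step_10"] = germ
    row["gametes2"] = "?" if g3 == "?" else ("iso" if g3 == "iso" else "aniso")
    if unknown_sexual:
        for c in _SEXUAL:
            row[c] = "?"
    if hatch_unknown:
        row["meiotic_hatching"] = "?"
    return row


_GONVOLV = (1, 3, 4, 5, 6)  # Kirk steps fixed in the Goniaceae+Volvocaceae ancestor
_VOLVOCACEAN = (1, 3, 4, 5, 6, 7, 8)  # plus complete inversion and volume

_TIP_TRAITS = {
    "Chlamydomonas_reinhardtii": _tip(),
    "Vitreochlamys_ordinata": _tip(unknown_sexual=True),
    "Basichlamys_sacculifera": _tip("multi", kirk=(1, 3, 5, 6), hatch_unknown=True),
    "Tetrabaena_socialis_NIES571": _tip("multi", kirk=(1, 3, 5, 6)),
    "Tetrabaena_socialis_NIES691": _tip("multi", kirk=(1, 3, 5, 6)),
    "Gonium_pectorale": _tip("multi", inversion="partial", kirk=(1, 2, 3, 4, 5, 6)),
    "Astrephomene_gubernaculifera": _tip(
        "multi", spheroid="1", kirk=_GONVOLV, soma="1", hatch="reduced"),
    "Volvox_rousseletii": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="oog", soma="1", germ="1", hatch="reduced", mating="monoecy",
        internal="1", extraf="1"),
    "Volvox_barberi": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="oog", soma="1", germ="1", hatch="reduced", mating="monoecy",
        internal="1", extraf="1"),
    "Pandorina_morum": _tip(
        "multi", spheroid="1", inversion="complete", kirk=(1, 3, 4, 5, 6, 7),
        hatch="reduced"),
    "Volvulina_steinii": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        hatch="reduced"),
    "Platydorina_caudata": _tip(
        "multi", spheroid="0", inversion="complete", kirk=(1, 3, 4, 5, 6, 7),
        g3="aniso", hatch="reduced"),
    "Colemanosphaera_charkowiensis": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced"),
    "Yamagishiella_unicocca": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        hatch="reduced"),
    "Eudorina_elegans": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced", internal="1"),
    "Pleodorina_thompsonii": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        soma="1", unknown_sexual=True),
    "Eudorina_elegans_UTEX1193": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced", internal="1"),
    "Eudorina_cylindrica": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced", internal="1"),
    "Volvox_aureus": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="oog", soma="1", germ="1", hatch="reduced", internal="1"),
    "Pleodorina_japonica": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", soma="1", germ="0", hatch="reduced", internal="1"),
    "Volvox_africanus": _tip(
        "multi", spheroid="1", inversion="complete",
        kirk=_VOLVOCACEAN + (11, 12), g3="oog", soma="1", germ="1",
        hatch="reduced", mating="monoecy", internal="1", extraf="1", dwarf="1"),
    "Volvox_obversus": _tip(
        "multi", spheroid="1", inversion="complete",
        kirk=_VOLVOCACEAN + (11, 12), g3="oog", soma="1", germ="1",
        hatch="reduced", internal="1", extraf="1"),
    "Volvox_carteri": _tip(
        "multi", spheroid="1", inversion="complete",
        kirk=_VOLVOCACEAN + (11, 12), g3="oog", soma="1", germ="1",
        hatch="reduced", internal="1", extraf="1", dwarf="1"),
    "Eudorina_unicocca": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced", internal="1"),
    "Pleodorina_starrii": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", soma="1", hatch="reduced", internal="1"),
    "Eudorina_elegans_NIES456": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="aniso", hatch="reduced", internal="1"),
    "Volvox_gigas": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="oog", soma="1", germ="1", hatch="reduced", internal="1"),
    "Volvox_powersii": _tip(
        "multi", spheroid="1", inversion="complete", kirk=_VOLVOCACEAN,
        g3="oog", soma="1", germ="1", hatch="reduced", internal="1"),
}

# provenance: the main-text statement behind each character's codings
_PROVENANCE = {
    "cellularity": "two independent origins of multicellularity: Tetrabaenaceae and Goniaceae + Volvocaceae; Chlamydomonas and Vitreochlamys are unicells",
    "spheroid": "spheroidal body plan arose independently twice (Astrephomene; Volvocaceae), with diminished/flattened forms in Platydorina",
    "inversion": "inversion absent in unicells, Tetrabaenaceae and Astrephomene; partial in Gonium; complete in the Volvocaceae",
    "gametes3": "Pandorina, Volvulina, Yamagishiella isogamous; Colemanosphaera, Eudorina, Platydorina anisogamous; Pleodorina anisogamous; Volvox oogamous",
    "gametes2": "two-state recoding of the gamete system (anisogamy includes oogamy)",
    "somatic_cells": "somatic differentiation in Astrephomene, section Volvox, P. thompsonii, the Volvox + P. japonica clade, and P. starrii + V. gigas; lost in the Eudorina lineage sister to V. gigas + V. powersii",
    "germ_cells": "specialized germ cells only in Volvox; lost once in P. japonica",
    "meiotic_hatching": "C. reinhardtii, Tetrabaena and Gonium release all four gone cells; reduced to one gone cell in Astrephomene and the Volvocaceae",
    "mating_system": "section Volvox ancestor became monoecious and selfing; V. africanus independently monoecious",
    "internal_fert": "internal fertilization gained in section Volvox and in the EVP clade",
    "extrafertile_females": "extrafertile females in section Volvox and the V. carteri + V. africanus ancestor",
    "dwarf_males": "dwarf males in the V. carteri + V. africanus ancestor with loss in V. obversus",
    **{f"kirk_step_{i}": "developmental steps coded from the stepwise gains described for the Tetrabaenaceae, Goniaceae + Volvocaceae, Gonium, Volvocaceae and Volvox ancestors" for i in range(1, 13)},
}


def volvocine_traits() -> tuple[TraitMatrix, pd.DataFrame]:
    """Trait matrix and per-cell provenance table for the fixture taxa."""
    data = pd.DataFrame.from_dict(_TIP_TRAITS, orient="index")[_CHARACTERS]
    tm = TraitMatrix(data=data, state_spaces=dict(_STATE_SPACES))
    rows = []
    for taxon, row in _TIP_TRAITS.items():
        for char in _CHARACTERS:
            state = row[char]
            source = (
                "not stated in main text" if state == "?" else _PROVENANCE[char]
            )
            rows.append(
                {"taxon": taxon, "character": char, "state": state, "source": source}
            )
    return tm, pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Archaeplastida fossil calibration table (14 rows), age specs as printed.
# Anchor tip pairs are representative members of each calibrated clade;
# the calibrated clades are published without named anchor tips, so these
# representative choices are recorded here as part of the fixture.
# ----------------------------------------------------------------------
_TABLE1 = """\
name\ttip_a\ttip_b\tage_spec
Bangiomorpha\tPorphyra_umbilicalis\tCyanidioschyzon_merolae\t1047 +13/-17
Oldest_Florideophycidae\tChondrus_crispus\tPorphyra_umbilicalis\t609 +/-5
Oldest_Zygnemataceae\tZygnema_circumcarinatum\tSpirogyra_pratensis\tMIN: 350
First_Land_Plants\tMarchantia_polymorpha\tArabidopsis_thaliana\tMIN: 480
Oldest_Tracheophytes\tSelaginella_moellendorffii\tArabidopsis_thaliana\t423-419
Fern_Seed_Plant_Split\tCeratopteris_richardii\tArabidopsis_thaliana\tMIN: 385
Gymnosperm_Angiosperm_Split\tPinus_taeda\tArabidopsis_thaliana\t330-323
Amborella_Nymphaeales_Split\tAmborella_trichopoda\tArabidopsis_thaliana\t129-125
Chloranthaceae_Magnoliid_Split\tChloranthus_spicatus\tArabidopsis_thaliana\tMIN: 125
Monocot_Eudicot_Split\tOryza_sativa\tArabidopsis_thaliana\tMIN: 113
Botryococcus_braunii\tBotryococcus_braunii\tChlamydomonas_reinhardtii\t358-356
Proterocladus\tUlva_mutabilis\tChlamydomonas_reinhardtii\t1056-948
Vermiporella\tPseudendoclonium_akinetum\tUlva_mutabilis\t470-458
Protocodium\tCodium_fragile\tCaulerpa_lentillifera\tMIN: 541
"""


def archaeplastida_calibrations() -> CalibrationTable:
    """The 14-fossil calibration table with soft-bound defaults."""
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        fh.write(_TABLE1)
        path = fh.name
    try:
        return read_calibrations(path)
    finally:
        Path(path).unlink(missing_ok=True)


# ----------------------------------------------------------------------
@dataclass
class VolvocineFixture:
    tree: RootedTree
    named_nodes: dict[str, int]
    traits: TraitMatrix
    provenance: pd.DataFrame
    calibrations: CalibrationTable
    node_hpd: dict[str, tuple[float, float]]

    def age(self, name: str) -> float:
        return float(self.tree.ages[self.named_nodes[name]])


def build_volvocine_fixture(outdir: Path | str | None = None) -> VolvocineFixture:
    """Assemble the fixture; optionally write its files under ``outdir``.

    Files written: ``volvocine_chronogram.nwk`` (branch lengths in My),
    ``volvocine_traits.tsv`` + ``volvocine_trait_states.tsv``,
    ``volvocine_provenance.tsv``, ``archaeplastida_calibrations.tsv``.
    """
    tree, named = volvocine_tree()
    traits, provenance = volvocine_traits()
    cals = archaeplastida_calibrations()
    fixture = VolvocineFixture(tree, named, traits, provenance, cals, dict(NODE_HPD))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_newick(tree, outdir / "volvocine_chronogram.nwk")
        write_traits(traits, outdir / "volvocine_traits.tsv")
        lines = [f"{c}\t{','.join(s)}" for c, s in traits.state_spaces.items()]
        (outdir / "volvocine_trait_states.tsv").write_text("\n".join(lines) + "\n")
        provenance.to_csv(outdir / "volvocine_provenance.tsv", sep="\t", index=False)
        write_calibrations(cals, outdir / "archaeplastida_calibrations.tsv")
    return fixture
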