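"""Synthetic default compound library and shRNA gene panel.

The full-scale screen geometry is 80 targeted agents (22 of them
FDA-approved) crossed with 36 knockdown lines plus one control-shRNA
line. The published appendix listing the exact library is not
redistributed here; this module ships a *synthetic* stand-in panel of
real, plausible kinase-directed compounds and cancer-fitness genes with
the same geometry, for simulation and testing. It is not the screened
library.

Per-compound potency parameters (Emax, EC50, Hill slope) and per-gene
knockdown baseline kill fractions are drawn once from a fixed generator
seed so the panel is identical in every session.
"""

from __future__ import annotations

import numpy as np

from .screen_model import CellLineRecord, CompoundRecord, ScreenDesign

# 22 FDA-approved targeted agents (name, primary target annotation)
_FDA_APPROVED = [
    ("sunitinib", "VEGFR/PDGFR/KIT"),
    ("sorafenib", "RAF/VEGFR"),
    ("pazopanib", "VEGFR/PDGFR"),
    ("axitinib", "VEGFR"),
    ("cabozantinib", "MET/VEGFR2"),
    ("lenvatinib", "VEGFR/FGFR"),
    ("everolimus", "mTOR"),
    ("temsirolimus", "mTOR"),
    ("erlotinib", "EGFR"),
    ("gefitinib", "EGFR"),
    ("lapatinib", "EGFR/HER2"),
    ("imatinib", "ABL/KIT/PDGFR"),
    ("dasatinib", "ABL/SRC"),
    ("nilotinib", "ABL"),
    ("crizotinib", "ALK/MET"),
    ("ceritinib", "ALK"),
    ("vemurafenib", "BRAF V600E"),
    ("dabrafenib", "BRAF"),
    ("trametinib", "MEK1/2"),
    ("palbociclib", "CDK4/6"),
    ("ruxolitinib", "JAK1/2"),
    ("ibrutinib", "BTK"),
]

# 58 tool/investigational compounds
_TOOL_COMPOUNDS = [
    ("KU-60019", "ATM"),
    ("KU-55933", "ATM"),
    ("SGC-CK2-1", "CK2"),
    ("TBB", "CK2"),
    ("VE-821", "ATR"),
    ("AZD6738", "ATR"),
    ("AZD7762", "CHK1/2"),
    ("LY2603618", "CHK1"),
    ("MK-1775", "WEE1"),
    ("BI-2536", "PLK1"),
    ("volasertib", "PLK1"),
    ("alisertib", "Aurora A"),
    ("barasertib", "Aurora B"),
    ("dinaciclib", "CDK1/2/5/9"),
    ("flavopiridol", "pan-CDK"),
    ("ribociclib", "CDK4/6"),
    ("THZ1", "CDK7"),
    ("AZD4573", "CDK9"),
    ("buparlisib", "pan-PI3K"),
    ("alpelisib", "PI3Kalpha"),
    ("idelalisib", "PI3Kdelta"),
    ("MK-2206", "AKT"),
    ("ipatasertib", "AKT"),
    ("AZD8055", "mTORC1/2"),
    ("sapanisertib", "mTORC1/2"),
    ("rapamycin", "mTOR"),
    ("PF-4708671", "S6K1"),
    ("selumetinib", "MEK1/2"),
    ("ulixertinib", "ERK1/2"),
    ("SCH772984", "ERK1/2"),
    ("saracatinib", "SRC"),
    ("bosutinib", "SRC/ABL"),
    ("defactinib", "FAK"),
    ("PF-573228", "FAK"),
    ("fedratinib", "JAK2"),
    ("tofacitinib", "JAK3"),
    ("stattic", "STAT3"),
    ("AZD4547", "FGFR1-3"),
    ("erdafitinib", "pan-FGFR"),
    ("linsitinib", "IGF1R"),
    ("BMS-754807", "IGF1R/IR"),
    ("quizartinib", "FLT3"),
    ("gilteritinib", "FLT3/AXL"),
    ("savolitinib", "MET"),
    ("capmatinib", "MET"),
    ("lorlatinib", "ALK/ROS1"),
    ("entrectinib", "TRK/ROS1"),
    ("larotrectinib", "TRK"),
    ("GSK2334470", "PDK1"),
    ("LY2584702", "p70S6K"),
    ("CHIR-99021", "GSK3"),
    ("SB-216763", "GSK3"),
    ("Y-27632", "ROCK"),
    ("GSK269962A", "ROCK1/2"),
    ("IPA-3", "PAK1"),
    ("FRAX597", "PAK1-3"),
    ("OTS964", "TOPK"),
    ("CFI-400945", "PLK4"),
]

# 36 genes required for cancer-cell fitness (kinases and pathway nodes)
GENE_PANEL = [
    "CSNK2A1", "ATM", "ATR", "CHEK1", "CHEK2", "WEE1",
    "PLK1", "AURKA", "AURKB", "CDK1", "CDK4", "CDK6",
    "CDK9", "EGFR", "ERBB2", "MET", "ALK", "BRAF",
    "RAF1", "MAP2K1", "MAPK1", "PIK3CA", "AKT1", "MTOR",
    "RPS6KB1", "SRC", "ABL1", "JAK2", "FGFR1", "PDGFRB",
    "KDR", "FLT3", "KIT", "RET", "IGF1R", "PTK2",
]

_PANEL_SEED = 20210213  # fixed: the panel must be identical across sessions


def default_compounds() -> list[CompoundRecord]:
    """The 80-compound synthetic library (22 FDA-approved), manifest order."""
    records = []
    for i, (name, target) in enumerate(_FDA_APPROVED + _TOOL_COMPOUNDS, start=1):
        records.append(
            CompoundRecord(
                compound_id=f"CPD{i:03d}",
                name=name,
                target_annotation=target,
                fda_approved=(name, target) in _FDA_APPROVED,
            )
        )
    return records


def default_lines() -> list[CellLineRecord]:
    """One control-shRNA line plus 36 targeted knockdown lines."""
    lines = [CellLineRecord(line_id="shCTL", gene_symbol="CTL", role="control")]
    lines += [
        CellLineRecord(line_id=f"sh{gene}", gene_symbol=gene, role="targeted")
        for gene in GENE_PANEL
    ]
    return lines


def default_design() -> ScreenDesign:
    """Full-scale design: 80 compounds x (36 targeted + 1 control) lines,
    1/5/20 uM, Hoechst + PrestoBlue, 8 + 8 control wells per plate."""
    return ScreenDesign(compounds=default_compounds(), lines=default_lines())


def compound_id_of(name: str) -> str:
    """Look up the synthetic manifest id of a compound by name."""
    for c in default_compounds():
        if c.name == name:
            return c.compound_id
    raise KeyError(name)


def default_potency_params() -> dict[str, tuple[float, float, float]]:
    """Per-compound (Emax kill fraction, EC50 uM, Hill slope).

    Drawn once from a fixed seed: Emax uniform on [0.05, 0.6], EC50
    log-uniform on [0.5, 50] uM, Hill slope uniform on [0.8, 2.0] --
    typical single-agent potencies in a 48 h viability assay where only
    the positive control approaches maximal kill.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    params = {}
    for c in default_compounds():
        emax = float(rng.uniform(0.05, 0.6))
        ec50 = float(np.exp(rng.uniform(np.log(0.5), np.log(50.0))))
        hill = float(rng.uniform(0.8, 2.0))
        params[c.compound_id] = (emax, ec50, hill)
    return params


def default_knockdown_kill() -> dict[str, float]:
    """Per-gene baseline kill fraction of the knockdown alone.

    Small (uniform on [0, 0.05], fixed seed): stable knockdown lines are
    viable by construction, but fitness genes carry a mild cost.
    """
    rng = np.random.default_rng(_PANEL_SEED + 1)
    return {gene: float(rng.uniform(0.0, 0.05)) for gene in GENE_PANEL}
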