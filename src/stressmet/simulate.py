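"""Synthetic study generator with known ground truth.

Emulates the shape of the repeated-social-defeat plasma metabolomics
experiment: 330 named metabolites organised into 65 subpathways under 7
superpathways (Carbohydrate 21, Amino acid 98, Lipid 134, plus Peptide,
Nucleotide, Cofactors and vitamins, Xenobiotics), a full 2 x 2 x 2 design
(treatment x regimen x timepoint) with 5-6 mice per cell, log-normal
intensities, missing-at-random dropout, and multiplicative treatment/time
effects injected into chosen metabolite sets or pathways.

Every injected effect is recorded per canonical comparison in a truth
table, so downstream tests can check sign and magnitude recovery.  A single
integer seed drives one root :class:`numpy.random.Generator`; draw order is
fixed (log-means, log-sds, base noise, effect sign assignment per effect in
listed order, missingness mask), so runs are byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    REGIMENS,
    TIMEPOINTS,
    TREATMENTS,
    ComparisonSpec,
    MetaboliteMatrix,
    PathwayMap,
    SampleDesign,
    canonical_comparisons,
)

# Default pathway structure: (superpathway, subpathway, n members).
# Sizes sum to 330 over 65 subpathways; the three fuel superpathways carry
# 21 / 98 / 134 metabolites.  Names follow common untargeted-panel usage.
_SUB = [
    ("Carbohydrate", "Glycolysis and pyruvate metabolism", 6),
    ("Carbohydrate", "Pentose metabolism", 6),
    ("Carbohydrate", "Fructose, mannose and galactose metabolism", 5),
    ("Carbohydrate", "Aminosugar metabolism", 4),
    ("Amino acid", "Glycine, serine and threonine metabolism", 10),
    ("Amino acid", "Urea cycle; arginine-, proline-, metabolism", 9),
    ("Amino acid", "Branched-chain amino acid metabolism", 8),
    ("Amino acid", "Lysine metabolism", 8),
    ("Amino acid", "Phenylalanine and tyrosine metabolism", 7),
    ("Amino acid", "Tryptophan metabolism", 7),
    ("Amino acid", "Methionine and cysteine metabolism", 7),
    ("Amino acid", "Alanine and aspartate metabolism", 6),
    ("Amino acid", "Glutamate metabolism", 6),
    ("Amino acid", "Histidine metabolism", 6),
    ("Amino acid", "Glutathione metabolism", 6),
    ("Amino acid", "Creatine metabolism", 5),
    ("Amino acid", "Polyamine metabolism", 5),
    ("Amino acid", "Guanidino and acetamido metabolism", 4),
    ("Amino acid", "Felinine metabolism", 4),
    ("Lipid", "Lysophospholipid", 10),
    ("Lipid", "Long chain fatty acid", 10),
    ("Lipid", "Glycerophospholipid metabolism", 9),
    ("Lipid", "Sphingolipid metabolism", 9),
    ("Lipid", "Primary bile acid metabolism", 8),
    ("Lipid", "Secondary bile acid metabolism", 8),
    ("Lipid", "Medium chain fatty acid", 7),
    ("Lipid", "Polyunsaturated fatty acid", 7),
    ("Lipid", "Fatty acid, monohydroxy", 7),
    ("Lipid", "Fatty acid, dicarboxylate", 7),
    ("Lipid", "Carnitine metabolism", 6),
    ("Lipid", "Ketone bodies", 6),
    ("Lipid", "Sterol and steroid", 6),
    ("Lipid", "Glycerolipid metabolism", 6),
    ("Lipid", "Inositol metabolism", 6),
    ("Lipid", "Phospholipid ethanolamine", 5),
    ("Lipid", "Eicosanoid", 5),
    ("Lipid", "Endocannabinoid", 4),
    ("Lipid", "Plasmalogen", 4),
    ("Lipid", "Monoacylglycerol", 4),
    ("Peptide", "Dipeptide", 3),
    ("Peptide", "Gamma-glutamyl amino acid", 3),
    ("Peptide", "Acetylated peptides", 3),
    ("Peptide", "Fibrinogen cleavage peptide", 3),
    ("Nucleotide", "Purine metabolism, (hypo)xanthine/inosine", 5),
    ("Nucleotide", "Purine metabolism, adenine containing", 4),
    ("Nucleotide", "Purine metabolism, guanine containing", 4),
    ("Nucleotide", "Pyrimidine metabolism, uracil containing", 3),
    ("Nucleotide", "Pyrimidine metabolism, cytidine containing", 2),
    ("Nucleotide", "Pyrimidine metabolism, thymine containing", 2),
    ("Cofactors and vitamins", "Nicotinate and nicotinamide metabolism", 3),
    ("Cofactors and vitamins", "Pantothenate and CoA metabolism", 3),
    ("Cofactors and vitamins", "Ascorbate and aldarate metabolism", 3),
    ("Cofactors and vitamins", "Tocopherol metabolism", 2),
    ("Cofactors and vitamins", "Riboflavin metabolism", 2),
    ("Cofactors and vitamins", "Heme metabolism", 2),
    ("Xenobiotics", "Benzoate metabolism", 4),
    ("Xenobiotics", "Phenol and cresol metabolism", 4),
    ("Xenobiotics", "Food component/plant", 3),
    ("Xenobiotics", "Xanthine metabolism", 3),
    ("Xenobiotics", "Drug metabolism", 3),
    ("Xenobiotics", "Chemical", 3),
    ("Xenobiotics", "Sugar substitute", 3),
    ("Xenobiotics", "Bacterial/fungal", 3),
    ("Xenobiotics", "Indole derivatives", 2),
    ("Xenobiotics", "Krebs cycle analogs", 2),
]

# Gut-microbiota-derived plasma compounds; members of the two gut-facing
# xenobiotic subpathways in the default structure.
GUT_METABOLITES = (
    "phenylpropionylglycine",
    "hippurate",
    "3-phenylpropionate",
    "phenol sulfate",
    "p-cresol sulfate",
)


def default_pathway_table() -> pd.DataFrame:
    """Metabolite annotation table for the default 330-metabolite panel."""
    rows = []
    for sup, sub, size in _SUB:
        for i in range(size):
            rows.append((f"{sub}__m{i + 1:02d}", sup, sub))
    df = pd.DataFrame(rows, columns=["metabolite_id", "superpathway", "subpathway"])
    df = df.set_index("metabolite_id")
    # give the gut-derived compounds their real names
    gut_slots = [m for m in df.index
                 if df.loc[m, "subpathway"] in ("Benzoate metabolism", "Phenol and cresol metabolism")]
    renames = dict(zip(gut_slots, GUT_METABOLITES))
    return df.rename(index=renames)


@dataclass(frozen=True)
class EffectSpec:
    """One injected multiplicative effect.

    target: ("metabolites", ids) | ("subpathway", name) | ("superpathway", name)
    scope:  treatment_acute  — AggE samples at the acute time point
            treatment_chronic — AggE samples at the chronic time point
            time             — all acute samples (both treatments)
    log_fc: natural-log fold change applied to targeted samples
    coherence: fraction of target metabolites receiving the stated sign;
               the remainder get the opposite sign.
    """

    target: tuple[str, object]
    scope: str
    log_fc: float
    coherence: float = 1.0

    def __post_init__(self) -> None:
        if self.scope not in ("treatment_acute", "treatment_chronic", "time"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if not math.isfinite(self.log_fc):
            raise ValueError("log_fc must be finite")
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError("coherence must be in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_per_cell: int = 6
    log_mean_sd: float = 1.0            # spread of metabolite log-means
    log_sd_range: tuple[float, float] = (0.2, 0.6)  # per-metabolite log-sd
    missing_rate: float = 0.05
    n_unidentified: int = 0
    pathway_table: pd.DataFrame = field(default_factory=default_pathway_table)
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("n_per_cell must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_metabolites(self) -> int:
        return len(self.pathway_table) + self.n_unidentified


def _resolve_target(effect: EffectSpec, pathways: pd.DataFrame) -> list[str]:
    kind, val = effect.target
    if kind == "metabolites":
        ids = list(val)
        unknown = set(ids) - set(pathways.index)
        if unknown:
            raise KeyError(f"effect targets unknown metabolite(s): {sorted(unknown)[:5]}")
        return ids
    if kind == "subpathway":
        ids = list(pathways.index[pathways["subpathway"] == val])
    elif kind == "superpathway":
        ids = list(pathways.index[pathways["superpathway"] == val])
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    if not ids:
        raise KeyError(f"effect targets unknown {kind} {val!r}")
    return ids


def _build_design(n_per_cell: int) -> SampleDesign:
    rows = []
    for tr in TREATMENTS:
        for rg in REGIMENS:
            for tp in TIMEPOINTS:
                for i in range(n_per_cell):
                    rows.append((f"{tr}_{rg}_{tp}_{i + 1:02d}", tr, rg, tp))
    df = pd.DataFrame(rows, columns=["sample_id", "treatment", "regimen", "timepoint"])
    return SampleDesign(df.set_index("sample_id"))


def generate_study(
    cfg: GeneratorConfig,
) -> tuple[MetaboliteMatrix, SampleDesign, PathwayMap, pd.DataFrame]:
    """Draw one synthetic study.

    Returns (matrix, design, pathway map, truth table).  The truth table has
    one row per (metabolite, canonical comparison) with a non-zero injected
    log fold change of group A over group B.
    """
    rng = np.random.default_rng(cfg.seed)
    pathways = cfg.pathway_table.copy()
    if cfg.n_unidentified:
        extra = pd.DataFrame(
            {"superpathway": "Unidentified", "subpathway": "Unidentified"},
            index=[f"X-{i + 1:04d}" for i in range(cfg.n_unidentified)],
        )
        pathways = pd.concat([pathways, extra])
    mets = list(pathways.index)
    n_met = len(mets)

    design = _build_design(cfg.n_per_cell)
    samples = list(design.table.index)
    n_samp = len(samples)

    mu = rng.normal(0.0, cfg.log_mean_sd, size=n_met)
    sd = rng.uniform(*cfg.log_sd_range, size=n_met)
    log_x = mu + sd * rng.standard_normal((n_samp, n_met))

    # per-(sample, metabolite) additive log effect
    tr_col = design.table["treatment"].to_numpy()
    tp_col = design.table["timepoint"].to_numpy()
    scope_masks = {
        "treatment_acute": (tr_col == "AggE") & (tp_col == "acute"),
        "treatment_chronic": (tr_col == "AggE") & (tp_col == "chronic"),
        "time": tp_col == "acute",
    }
    met_pos = {m: j for j, m in enumerate(mets)}
    # truth accumulates the net injected log-FC per canonical comparison
    specs = canonical_comparisons(design)
    truth_lfc = np.zeros((n_met, len(specs)))
    labels = [s.label for s in specs]
    col = {lab: j for j, lab in enumerate(labels)}

    for eff in cfg.effects:
        targets = _resolve_target(eff, pathways)
        signs = np.ones(len(targets))
        n_flip = len(targets) - int(round(eff.coherence * len(targets)))
        if n_flip:
            flip = rng.choice(len(targets), size=n_flip, replace=False)
            signs[flip] = -1.0
        mask = scope_masks[eff.scope]
        for m_id, s in zip(targets, signs):
            j = met_pos[m_id]
            log_x[mask, j] += s * eff.log_fc
            if eff.scope == "treatment_acute":
                for rg in REGIMENS:
                    truth_lfc[j, col[f"AggE_vs_Ctrl|{rg}|acute"]] += s * eff.log_fc
                    truth_lfc[j, col[f"acute_vs_chronic|AggE|{rg}"]] += s * eff.log_fc
            elif eff.scope == "treatment_chronic":
                for rg in REGIMENS:
                    truth_lfc[j, col[f"AggE_vs_Ctrl|{rg}|chronic"]] += s * eff.log_fc
                    truth_lfc[j, col[f"acute_vs_chronic|AggE|{rg}"]] -= s * eff.log_fc
            else:  # time
                for tr in TREATMENTS:
                    for rg in REGIMENS:
                        truth_lfc[j, col[f"acute_vs_chronic|{tr}|{rg}"]] += s * eff.log_fc

    values = np.exp(log_x)
    if cfg.missing_rate > 0:
        miss = rng.random((n_samp, n_met)) < cfg.missing_rate
        values = np.where(miss, np.nan, values)

    matrix = MetaboliteMatrix(pd.DataFrame(values, index=samples, columns=mets))

    rows = np.argwhere(truth_lfc != 0.0)
    truth = pd.DataFrame(
        {
            "metabolite_id": [mets[i] for i, _ in rows],
            "comparison": [labels[j] for _, j in rows],
            "true_log_fc": [truth_lfc[i, j] for i, j in rows],
        }
    )
    return matrix, design, PathwayMap(pathways), truth


def preset_paper_like(seed: int = 0) -> GeneratorConfig:
    """Config bundling the study-shaped structure and headline effects:

    * the five gut-derived metabolites elevated 6.7-fold in AggE at the
      acute time point and 2.8-fold at the chronic time points;
    * lipid metabolites broadly elevated in AggE at chronic times;
    * amino-acid and carbohydrate metabolites suppressed at chronic times;
    * carbohydrates elevated in AggE at the acute time point;
    * conjugated bile acids lower acutely, higher after withdrawal.
    """
    effects = (
        EffectSpec(("metabolites", GUT_METABOLITES), "treatment_acute", math.log(6.7)),
        EffectSpec(("metabolites", GUT_METABOLITES), "treatment_chronic", math.log(2.8)),
        EffectSpec(("superpathway", "Carbohydrate"), "treatment_acute", math.log(1.5), coherence=0.8),
        EffectSpec(("superpathway", "Carbohydrate"), "treatment_chronic", -math.log(1.4), coherence=0.75),
        EffectSpec(("superpathway", "Amino acid"), "treatment_chronic", -math.log(1.4), coherence=0.75),
        EffectSpec(("superpathway", "Lipid"), "treatment_chronic", math.log(1.5), coherence=0.8),
        EffectSpec(("subpathway", "Primary bile acid metabolism"), "treatment_acute", -math.log(1.32)),
        EffectSpec(("subpathway", "Primary bile acid metabolism"), "treatment_chronic", math.log(3.12)),
    )
    return GeneratorConfig(effects=effects, seed=seed)


def strip_effects(cfg: GeneratorConfig) -> GeneratorConfig:
    """Null variant of a config: same structure, no injected effects."""
    return replace(cfg, effects=())
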