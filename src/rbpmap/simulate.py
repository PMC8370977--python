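"""Synthetic TMT 11-plex proximity-labeling experiments with planted truth.

Every stage of the filtering pipeline and every evaluation metric can be
exercised against a generated dataset whose class labels are known.  The
intensity model is log-normal: the log2 reporter value of a protein in a
channel is a protein-specific baseline plus a class- and channel-role-
specific enrichment effect plus Gaussian noise.  This is the standard
first-order approximation for TMT reporter data; it deliberately omits
ratio compression, isotopic impurity spillover, and co-isolation
interference.

Planted classes
---------------
compartment_rbp_tight        in-compartment RBP, crosslink-independent
                             (enriched even in the omit-crosslink control)
compartment_rbp_fa_dependent in-compartment RBP requiring crosslinking
off_compartment_rbp          RBP elsewhere in the cell (the curated
                             false-positive class; for reference designs it
                             is strongly labeled by the reference construct)
compartment_non_rbp          in-compartment protein with no RNA binding
glycoprotein                 secretory-pathway contaminant enriched by phase
                             separation independent of RNA binding; survives
                             ratiometric filtering and must be removed by
                             the glycoprotein annotation list
background                   everything else (detector background)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .metrics import AnnotationResource
from .quant_io import ExperimentDesign, QuantTable, RatioPair

CLASS_NAMES = (
    "compartment_rbp_tight",
    "compartment_rbp_fa_dependent",
    "off_compartment_rbp",
    "compartment_non_rbp",
    "glycoprotein",
    "background",
)

_GENE_PREFIX = {
    "compartment_rbp_tight": "TIGHT",
    "compartment_rbp_fa_dependent": "FADEP",
    "off_compartment_rbp": "OFFC",
    "compartment_non_rbp": "NONRBP",
    "glycoprotein": "GLYC",
    "background": "BKG",
}


@dataclass
class SimConfig:
    """Study conditions for one simulated multiplex experiment.

    ``effect`` is the mean log2 enrichment of each class in experimental
    channels relative to background controls; ``reference_effect`` is the
    analogous enrichment produced by the spatial-reference construct.
    Tight binders and glycoproteins keep their full enrichment in
    omit-crosslink control channels; crosslink-dependent binders drop to
    baseline there.  ``detect_fail_frac`` of proteins are emitted with a
    peptide count or protein score below the detection filter.
    """

    design: ExperimentDesign
    n_per_class: dict[str, int] = field(default_factory=dict)
    effect: dict[str, float] = field(default_factory=dict)
    reference_effect: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.5
    base_log2_mean: float = 17.0
    base_log2_sd: float = 1.5
    seed: int = 0
    detect_fail_frac: float = 0.08
    tp_list_frac: float = 0.4       # fraction of compartment RBPs on the curated TP list
    fp_list_frac: float = 0.5       # fraction of off-compartment RBPs on the FP list
    gold_frac: float = 0.3          # fraction of compartment RBPs in the gold standard
    compendium_noise_frac: float = 0.05   # background genes wrongly annotated as RBPs

    def __post_init__(self):
        for cls in self.n_per_class:
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown class {cls!r}")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for d in (self.effect, self.reference_effect):
            if any(not np.isfinite(v) for v in d.values()):
                raise ValueError("effects must be finite")


@dataclass
class SyntheticTruth:
    """Ground-truth class labels and emitted-list memberships per gene."""

    table: pd.DataFrame     # index gene_symbol; columns: class_label + membership flags

    def genes_of(self, class_label: str) -> set:
        t = self.table
        return set(t.index[t["class_label"] == class_label])

    @property
    def compartment_rbps(self) -> set:
        return self.genes_of("compartment_rbp_tight") | self.genes_of("compartment_rbp_fa_dependent")


def _class_channel_effect(cls: str, role: str, cfg: SimConfig) -> float:
    eff = cfg.effect.get(cls, 0.0)
    if role == "experimental":
        return eff
    if role == "background_control":
        return 0.0
    if role == "spatial_reference":
        return cfg.reference_effect.get(cls, 0.0)
    if role == "omit_crosslink_control":
        # phase separation retains tight binders and glycan-bearing
        # contaminants without chemical crosslinking
        return eff if cls in ("compartment_rbp_tight", "glycoprotein") else 0.0
    raise ValueError(f"unknown role {role!r}")


def generate(config: SimConfig) -> tuple[QuantTable, AnnotationResource, SyntheticTruth]:
    """Draw one experiment: quantification table, annotation lists, truth labels.

    Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    n_total = sum(config.n_per_class.values())
    if n_total == 0:
        raise ValueError("zero total proteins configured")
    design = config.design
    labels = design.channel_labels()
    roles = dict(design.channels)

    genes, classes = [], []
    for cls in CLASS_NAMES:
        for i in range(config.n_per_class.get(cls, 0)):
            genes.append(f"{_GENE_PREFIX[cls]}{i + 1:04d}")
            classes.append(cls)
    genes = np.array(genes, dtype=object)
    classes = np.array(classes, dtype=object)

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n_total)
    chan_vals = {}
    for lab in labels:
        role = roles[lab]
        eff = np.array([_class_channel_effect(c, role, config) for c in classes])
        log2v = base + eff + rng.normal(0.0, config.noise_sd, size=n_total)
        chan_vals[lab] = np.exp2(log2v)

    # detection-filter metadata: a configurable fraction is emitted failing
    peptides = rng.poisson(6.0, size=n_total) + 2
    scores = 20.0 + rng.exponential(40.0, size=n_total)
    n_fail = int(round(config.detect_fail_frac * n_total))
    if n_fail:
        fail_idx = rng.choice(n_total, size=n_fail, replace=False)
        half = n_fail // 2
        peptides[fail_idx[:half]] = 1
        scores[fail_idx[half:]] = rng.uniform(0.0, 19.9, size=n_fail - half)

    data = pd.DataFrame({
        "protein_id": [f"SIM_{g}" for g in genes],
        "gene_symbol": genes,
        "n_distinct_peptides": peptides,
        "protein_score": scores,
        **chan_vals,
    })
    table = QuantTable(data, list(labels))

    truth_df = pd.DataFrame({"class_label": classes}, index=pd.Index(genes, name="gene_symbol"))
    by_class = {cls: set(truth_df.index[truth_df["class_label"] == cls]) for cls in CLASS_NAMES}
    compartment_rbps = by_class["compartment_rbp_tight"] | by_class["compartment_rbp_fa_dependent"]

    def sample(pool: set, frac: float) -> set:
        pool = sorted(pool)
        k = int(round(frac * len(pool)))
        if k == 0 or not pool:
            return set()
        return set(rng.choice(pool, size=min(k, len(pool)), replace=False))

    tp_bg = sample(compartment_rbps, config.tp_list_frac)
    fp_bg = sample(by_class["off_compartment_rbp"], config.fp_list_frac)
    has_reference = any(p.comparison_type == "reference" for p in design.comparisons)
    tp_ref = sample(compartment_rbps, config.tp_list_frac) if has_reference else None
    fp_ref = sample(by_class["off_compartment_rbp"], config.fp_list_frac) if has_reference else None

    rbp_compendium = (compartment_rbps | by_class["off_compartment_rbp"]
                      | sample(by_class["background"], config.compendium_noise_frac))
    compartment_set = compartment_rbps | by_class["compartment_non_rbp"]
    gold = sample(compartment_rbps, config.gold_frac)

    # a simple RNA-binding-domain annotation: some tight binders carry the
    # classical RRM, some crosslink-dependent binders a nonclassical domain
    rbd_map: dict[str, set] = {}
    for g in sorted(by_class["compartment_rbp_tight"]):
        if rng.random() < 0.6:
            rbd_map[g] = {"RRM"}
    for g in sorted(by_class["compartment_rbp_fa_dependent"]):
        if rng.random() < 0.4:
            rbd_map[g] = {"DEAD"}
    domain_classes = {"RRM": "classical", "KH": "classical",
                      "DEAD": "nonclassical", "NTF2": "nonclassical"}
    abundance = {g: float(2.0 ** b) for g, b in zip(genes, base)}

    annotations = AnnotationResource(
        tp_background=tp_bg, fp_background=fp_bg,
        tp_reference=tp_ref, fp_reference=fp_ref,
        glyco_set=set(by_class["glycoprotein"]),
        rbp_compendium=rbp_compendium,
        compartment_set=compartment_set,
        gold_standard=gold,
        rbd_map=rbd_map, domain_classes=domain_classes,
        abundance=abundance,
    )

    truth_df["in_tp_list"] = [g in tp_bg for g in truth_df.index]
    truth_df["in_fp_list"] = [g in fp_bg for g in truth_df.index]
    truth_df["in_glyco_list"] = [g in annotations.glyco_set for g in truth_df.index]
    truth_df["in_gold_standard"] = [g in gold for g in truth_df.index]
    truth_df["in_compendium"] = [g in rbp_compendium for g in truth_df.index]
    return table, annotations, SyntheticTruth(truth_df)


# ---------------------------------------------------------------------------
# preset plex designs
# ---------------------------------------------------------------------------

def _nucleus_design() -> ExperimentDesign:
    # 11-plex slots 1-6 of the nucleus/nucleolus cassette: omit-enzyme,
    # omit-H2O2 and omit-crosslink controls plus three nuclear replicates
    return ExperimentDesign(
        channels=[
            ("126C", "background_control"),        # omit enzyme
            ("127N", "background_control"),        # omit H2O2
            ("127C", "omit_crosslink_control"),    # omit FA
            ("128N", "experimental"),
            ("128C", "experimental"),
            ("129N", "experimental"),
        ],
        comparisons=[
            RatioPair("128N", "126C", 1, "background"),
            RatioPair("128C", "127N", 2, "background"),
            RatioPair("129N", "127N", 3, "background"),
        ],
        min_replicates_k=2,
    )


def _nucleolus_design() -> ExperimentDesign:
    # nucleolar replicates are compared both to enrichment controls and to
    # the whole-nucleus construct serving as spatial reference
    return ExperimentDesign(
        channels=[
            ("126C", "background_control"),        # omit enzyme
            ("129C", "background_control"),        # omit H2O2 (nucleolar arm)
            ("130N", "omit_crosslink_control"),    # omit FA (nucleolar arm)
            ("128N", "spatial_reference"),         # whole-nucleus replicate 1
            ("128C", "spatial_reference"),         # whole-nucleus replicate 2
            ("129N", "spatial_reference"),         # whole-nucleus replicate 3
            ("130C", "experimental"),
            ("131N", "experimental"),
            ("131C", "experimental"),
        ],
        comparisons=[
            RatioPair("130C", "126C", 1, "background"),
            RatioPair("130C", "128N", 1, "reference"),
            RatioPair("131N", "129C", 2, "background"),
            RatioPair("131N", "128C", 2, "reference"),
            RatioPair("131C", "129C", 3, "background"),
            RatioPair("131C", "129N", 3, "reference"),
        ],
        min_replicates_k=3,
    )


def _omm_design(pur: bool) -> ExperimentDesign:
    # OMM cassette: two replicates per arm, omit-H2O2 backgrounds, and a
    # cytosol-targeted construct as spatial reference
    if not pur:
        channels = [
            ("126C", "background_control"),        # omit H2O2, basal
            ("127N", "omit_crosslink_control"),    # omit FA, basal
            ("127C", "experimental"),
            ("128N", "experimental"),
            ("131N", "spatial_reference"),         # cytosolic reference
        ]
        comparisons = [
            RatioPair("127C", "126C", 1, "background"),
            RatioPair("127C", "131N", 1, "reference"),
            RatioPair("128N", "126C", 2, "background"),
            RatioPair("128N", "131N", 2, "reference"),
        ]
    else:
        channels = [
            ("128C", "background_control"),        # omit H2O2, +PUR
            ("129N", "omit_crosslink_control"),    # omit FA, +PUR
            ("129C", "experimental"),
            ("130N", "experimental"),
            ("131C", "spatial_reference"),         # cytosolic reference
        ]
        comparisons = [
            RatioPair("129C", "128C", 1, "background"),
            RatioPair("129C", "131C", 1, "reference"),
            RatioPair("130N", "128C", 2, "background"),
            RatioPair("130N", "131C", 2, "reference"),
        ]
    return ExperimentDesign(channels=channels, comparisons=comparisons, min_replicates_k=2)


_DEFAULT_N = {
    "compartment_rbp_tight": 50,
    "compartment_rbp_fa_dependent": 100,
    "off_compartment_rbp": 100,
    "compartment_non_rbp": 100,
    "glycoprotein": 50,
    "background": 600,
}

_DEFAULT_EFFECT = {
    # off-compartment RBPs are not labeled by the targeted construct (e.g.
    # mitochondrial proteins vs a nuclear construct); in reference designs
    # their signal appears in the spatial-reference channels instead
    "compartment_rbp_tight": 2.0,
    "compartment_rbp_fa_dependent": 2.0,
    "off_compartment_rbp": 0.0,
    "compartment_non_rbp": 0.0,
    "glycoprotein": 2.0,
    "background": 0.0,
}

_REFERENCE_EFFECT = {
    "compartment_rbp_tight": 0.5,
    "compartment_rbp_fa_dependent": 0.5,
    "off_compartment_rbp": 2.0,
    "compartment_non_rbp": 0.0,
    "glycoprotein": 0.5,
    "background": 0.0,
}


def scenario_presets(seed: int = 0) -> dict[str, SimConfig]:
    """Named study-condition presets mirroring the three plex layouts.

    ``nucleus``: three replicates, single background comparison each.
    ``nucleolus``: three replicates, dual comparison against background and
    a whole-nucleus spatial reference, all-replicate intersection.
    ``omm_basal`` / ``omm_pur``: two replicates each, dual comparison against
    an omit-H2O2 control and a cytosolic spatial reference.
    """
    return {
        "nucleus": SimConfig(
            design=_nucleus_design(),
            n_per_class=dict(_DEFAULT_N),
            effect=dict(_DEFAULT_EFFECT),
            reference_effect={},
            seed=seed,
        ),
        "nucleolus": SimConfig(
            design=_nucleolus_design(),
            n_per_class=dict(_DEFAULT_N),
            effect=dict(_DEFAULT_EFFECT),
            reference_effect=dict(_REFERENCE_EFFECT),
            seed=seed,
        ),
        "omm_basal": SimConfig(
            design=_omm_design(pur=False),
            n_per_class=dict(_DEFAULT_N),
            effect=dict(_DEFAULT_EFFECT),
            reference_effect=dict(_REFERENCE_EFFECT),
            seed=seed,
        ),
        "omm_pur": SimConfig(
            design=_omm_design(pur=True),
            n_per_class=dict(_DEFAULT_N),
            # puromycin disassembles polysomes: binders that engage RNA via
            # translation lose most of their enrichment, so the +PUR
            # proteome is smaller and largely a subset of the basal one;
            # tight (ribosome-independent) binders persist at full strength
            effect={**_DEFAULT_EFFECT, "compartment_rbp_fa_dependent": 1.0},
            reference_effect=dict(_REFERENCE_EFFECT),
            seed=seed,
        ),
    }


def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """One named preset, optionally with field overrides."""
    presets = scenario_presets(seed=seed)
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = presets[name]
    return replace(cfg, **overrides) if overrides else cfg
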