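"""Synthetic multi-study paired rhizosphere/bulk data with known ground truth.

The generator emulates the inputs of a multi-study 16S amplicon synthesis:
several independent studies, each contributing paired rhizosphere and bulk-soil
sample groups drawn from a shared regional species pool. It is a stylised
stand-in for observational survey data — distributional choices (log-normal
base composition, additive study random effect on the log-ratio scale,
coalescent tree) are documented in docs/methods.md and are not claims about
real soil communities.

Model
-----
* Base composition: log-normal relative abundances (sigma configurable,
  default 1.5), giving the steep rank-abundance curve typical of 16S data.
* A configured fraction of taxa is differential between compartments, with
  per-taxon log-fold effects ``delta_i`` drawn from a configured range;
  a configured fraction of those are rhizosphere-enriched (positive delta).
* Study heterogeneity: a study-level random effect ``u_j ~ N(0, tau2)`` is
  added to each differential taxon's effect magnitude, so study-level true
  log response ratios vary with between-study variance of order ``tau2``.
* Per-sample latent noise is block-correlated (taxa are assigned to blocks,
  within-block correlation configurable) to induce co-occurrence structure.
* Counts: multinomial at a negative-binomial sequencing depth, so row sums
  equal the drawn depths exactly.
* Traits: rhizosphere-enriched taxa receive systematically higher rRNA operon
  copy numbers and toxin-antitoxin gene counts (copiotroph profile), depleted
  taxa higher sporulation gene counts (oligotroph profile).

Ground truth for every study-level variable is declared analytically from the
expected compartment compositions (see :meth:`GroundTruth.study_lnrr`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as rio

PHYLUM_POOL = [
    "Proteobacteria", "Bacteroidetes", "Actinobacteria", "Acidobacteria",
    "Chloroflexi", "Firmicutes", "Gemmatimonadetes", "Nitrospirae",
    "Planctomycetes", "Verrucomicrobia",
]

DIVERSITY_VARIABLES = ("richness", "shannon", "pielou", "faith_pd")
TRAIT_VARIABLES = ("operon_cwm", "toxin_antitoxin", "sporulation")


class ConfigurationError(ValueError):
    """Raised when a SynthConfig is internally inconsistent."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults define the standard study conditions."""

    n_studies: int = 12
    samples_per_group: int = 5
    n_taxa: int = 300
    depth_mean: float = 15000.0
    depth_dispersion: float = 20.0     # negative-binomial shape; larger = tighter
    frac_differential: float = 0.20
    effect_low: float = 0.8            # |log-fold| range of differential taxa
    effect_high: float = 2.0
    frac_enriched: float = 0.7         # of differential taxa, share enriched in rhizosphere
    tau2: float = 0.05                 # between-study variance on the log-ratio scale
    n_blocks: int = 10
    block_correlation: float = 0.7
    sample_sigma: float = 0.6          # per-sample log-abundance noise scale
    base_sigma: float = 1.5            # log-normal base composition scale
    operon_effect_slope: float = 1.0   # extra operon copies per unit positive log-fold
    ta_effect_slope: float = 1.2       # toxin-antitoxin Poisson rate per unit enrichment
    spor_effect_slope: float = 2.0     # sporulation Poisson rate per unit depletion
    truth_depth: int = 10000           # read depth at which expected richness/PD are declared
    seed: int = 0

    def validate(self) -> "SynthConfig":
        positive = {
            "n_studies": self.n_studies, "samples_per_group": self.samples_per_group,
            "n_taxa": self.n_taxa, "depth_mean": self.depth_mean,
            "depth_dispersion": self.depth_dispersion, "n_blocks": self.n_blocks,
            "truth_depth": self.truth_depth,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value}")
        for name, value in (("frac_differential", self.frac_differential),
                            ("frac_enriched", self.frac_enriched)):
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ConfigurationError(
                f"block_correlation must be in [0, 1), got {self.block_correlation}")
        if self.tau2 < 0:
            raise ConfigurationError(f"tau2 must be >= 0, got {self.tau2}")
        if not 0 < self.effect_low <= self.effect_high:
            raise ConfigurationError(
                f"need 0 < effect_low <= effect_high, got ({self.effect_low}, {self.effect_high})")
        if self.n_blocks > self.n_taxa:
            raise ConfigurationError("n_blocks cannot exceed n_taxa")
        return self


@dataclass
class GroundTruth:
    """Everything the generator knows that an analyst would have to estimate."""

    effects: pd.Series                 # per-taxon compartment log-fold effect
    tau2: float
    blocks: pd.Series                  # taxon -> correlation block id
    study_lnrr: pd.DataFrame           # study x variable true log response ratios
    min_effect: float                  # declared minimum |effect| of differential taxa

    @property
    def differential_taxa(self) -> pd.Index:
        return self.effects.index[self.effects != 0.0]

    def to_json(self) -> str:
        payload = {
            "tau2": self.tau2,
            "min_effect": self.min_effect,
            "effects": self.effects.to_dict(),
            "blocks": {k: int(v) for k, v in self.blocks.items()},
            "study_lnrr": {
                study: row.to_dict() for study, row in self.study_lnrr.iterrows()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        study_lnrr = pd.DataFrame.from_dict(payload["study_lnrr"], orient="index")
        return cls(
            effects=pd.Series(payload["effects"]).sort_index(),
            tau2=payload["tau2"],
            blocks=pd.Series(payload["blocks"]).sort_index(),
            study_lnrr=study_lnrr.sort_index(),
            min_effect=payload["min_effect"],
        )


@dataclass
class StudySet:
    """The bundle of artifacts one generator run emits."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    tree: TreeNode
    traits: pd.DataFrame
    function_map: dict
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _random_coalescent_newick(taxa: list[str], rng: np.random.Generator) -> str:
    """Random coalescent topology with exponential waiting-time branch lengths."""
    heights = {i: 0.0 for i in range(len(taxa))}
    newicks = {i: name for i, name in enumerate(taxa)}
    active = list(range(len(taxa)))
    next_id = len(taxa)
    height = 0.0
    while len(active) > 1:
        k = len(active)
        height += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        la = height - heights[a]
        lb = height - heights[b]
        newicks[next_id] = f"({newicks[a]}:{la:.8f},{newicks[b]}:{lb:.8f})"
        heights[next_id] = height
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return newicks[active[0]] + ";"


def _make_taxonomy(taxa: list[str], blocks: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Nested lineages; the phylum tracks the correlation block so that
    co-occurring taxa tend to share coarse taxonomy, as in real communities."""
    n_phyla = min(len(PHYLUM_POOL), int(blocks.max()) + 1)
    rows = []
    for idx, name in enumerate(taxa):
        phylum = PHYLUM_POOL[int(blocks[idx]) % n_phyla]
        genus_id = idx // 2
        rows.append({
            "Kingdom": "Bacteria",
            "Phylum": phylum,
            "Class": f"{phylum}_c{int(blocks[idx]):02d}",
            "Order": f"o{genus_id // 8:03d}",
            "Family": f"f{genus_id // 4:03d}",
            "Genus": f"g{genus_id:03d}",
            "Species": "",
        })
    return pd.DataFrame(rows, index=pd.Index(taxa, name="taxon_id"))


def _make_traits(effects: np.ndarray, cfg: SynthConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    n = len(effects)
    up = np.maximum(effects, 0.0)
    down = np.maximum(-effects, 0.0)
    operon = 1.0 + rng.lognormal(0.3, 0.35, size=n) + cfg.operon_effect_slope * up \
        + rng.normal(0.0, 0.15, size=n)
    operon = np.maximum(operon, 1.0)
    ta = rng.poisson(1.0 + cfg.ta_effect_slope * up)
    spor = rng.poisson(1.0 + cfg.spor_effect_slope * down)
    nsti = rng.exponential(0.5, size=n)
    return pd.DataFrame({
        "operon_copies": np.round(operon, 3),
        "toxin_antitoxin_genes": ta,
        "sporulation_genes": spor,
        "nsti": np.round(nsti, 4),
    })


def _make_function_map(taxonomy: pd.DataFrame, effects: pd.Series,
                       rng: np.random.Generator) -> dict:
    """Three marker functions: one loaded on enriched genera, one on depleted
    genera, and one broad function with a single phylum excluded."""
    genus_effect = effects.groupby(taxonomy["Genus"]).mean()
    enriched = genus_effect[genus_effect > 0].sort_values(ascending=False)
    depleted = genus_effect[genus_effect < 0].sort_values()
    fmap: dict[str, dict[str, list[tuple[str, str]]]] = {}
    if len(enriched) > 0:
        fmap["copiotroph_marker"] = {
            "include": [("Genus", g) for g in enriched.index[:15]],
            "exclude": [],
        }
    if len(depleted) > 0:
        fmap["oligotroph_marker"] = {
            "include": [("Genus", g) for g in depleted.index[:15]],
            "exclude": [],
        }
    excluded_phylum = taxonomy["Phylum"].value_counts().index[-1]
    fmap["broad_heterotrophy"] = {
        "include": [("Kingdom", "Bacteria")],
        "exclude": [("Phylum", excluded_phylum)],
    }
    return fmap


def _expected_compositions(base: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Softmax of log base + delta: the declared expected composition."""
    eta = np.log(base) + deltas
    eta -= eta.max()
    p = np.exp(eta)
    return p / p.sum()


def _edge_tip_probability_mass(tree: TreeNode, taxa: list[str],
                               p: np.ndarray) -> list[tuple[float, float]]:
    """(branch length, probability mass of tips below) for every edge."""
    pos = {t: i for i, t in enumerate(taxa)}
    masses = []
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            node._mass = p[pos[node.name]]
        else:
            node._mass = sum(c._mass for c in node.children)
        masses.append((node.length or 0.0, node._mass))
    for node in tree.postorder(include_self=False):
        del node._mass
    return masses


def _expected_variables(p: np.ndarray, traits: pd.DataFrame, taxonomy: pd.DataFrame,
                        fmap: dict, edge_masses_fn, depth: int) -> dict:
    """Declared true values of every downstream variable for a composition."""
    with np.errstate(divide="ignore", invalid="ignore"):
        log_p = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = float(-(p * log_p).sum())
    # expected observed richness at `depth` reads (with-replacement approximation)
    detect = 1.0 - np.exp(depth * np.log1p(-np.minimum(p, 1 - 1e-12)))
    richness = float(detect.sum())
    pielou = shannon / math.log(richness) if richness > 1 else float("nan")
    pd_total = 0.0
    for length, mass in edge_masses_fn(p):
        mass = min(mass, 1 - 1e-12)
        pd_total += length * (1.0 - math.exp(depth * math.log1p(-mass)))
    out = {
        "richness": richness,
        "shannon": shannon,
        "pielou": pielou,
        "faith_pd": pd_total,
        "operon_cwm": float(p @ traits["operon_copies"].to_numpy()),
        "toxin_antitoxin": float(p @ traits["toxin_antitoxin_genes"].to_numpy()),
        "sporulation": float(p @ traits["sporulation_genes"].to_numpy()),
    }
    from .traits import match_function_rules  # deferred: avoid import cycle
    for fname, rules in fmap.items():
        mask = match_function_rules(taxonomy, rules)
        out[f"fn_{fname}"] = float(p[mask.to_numpy()].sum())
    return out


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_study_set(config: SynthConfig) -> StudySet:
    """Generate one multi-study paired dataset with fully known ground truth."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    taxa = [f"ASV{i:04d}" for i in range(cfg.n_taxa)]
    base = rng.lognormal(0.0, cfg.base_sigma, cfg.n_taxa)
    base /= base.sum()

    n_diff = int(round(cfg.frac_differential * cfg.n_taxa))
    diff_idx = rng.choice(cfg.n_taxa, size=n_diff, replace=False)
    effects = np.zeros(cfg.n_taxa)
    if n_diff:
        signs = np.where(rng.random(n_diff) < cfg.frac_enriched, 1.0, -1.0)
        magnitudes = rng.uniform(cfg.effect_low, cfg.effect_high, n_diff)
        effects[diff_idx] = signs * magnitudes

    blocks = rng.integers(0, cfg.n_blocks, size=cfg.n_taxa)
    taxonomy = _make_taxonomy(taxa, blocks, rng)
    traits = _make_traits(effects, cfg, rng)
    traits.index = pd.Index(taxa, name="taxon_id")
    effects_s = pd.Series(effects, index=taxa, name="log_fold_effect")
    fmap = _make_function_map(taxonomy, effects_s, rng)
    newick = _random_coalescent_newick(taxa, rng)
    tree = TreeNode.read([newick], format="newick")

    def edge_masses_fn(p: np.ndarray):
        return _edge_tip_probability_mass(tree, taxa, p)

    sqrt_rho = math.sqrt(cfg.block_correlation)
    sqrt_1mrho = math.sqrt(1.0 - cfg.block_correlation)
    tau = math.sqrt(cfg.tau2)

    count_rows, meta_rows, sample_ids = [], [], []
    truth_rows = {}
    for j in range(cfg.n_studies):
        study = f"study{j:02d}"
        u_j = rng.normal(0.0, tau) if tau > 0 else 0.0
        # study random effect shifts each differential taxon's effect magnitude
        deltas_j = np.where(effects != 0.0, effects + u_j * np.sign(effects), 0.0)
        ecosystem = ("cropland", "grassland", "forest")[j % 3]
        study_ph = float(rng.normal(6.5, 0.6))
        study_lat = float(rng.uniform(-50, 60))
        for comp, shift in (("rhizosphere", deltas_j), ("bulk", np.zeros_like(deltas_j))):
            for s in range(cfg.samples_per_group):
                z_block = rng.normal(size=cfg.n_blocks)
                z = sqrt_rho * z_block[blocks] + sqrt_1mrho * rng.normal(size=cfg.n_taxa)
                eta = np.log(base) + shift + cfg.sample_sigma * z
                eta -= eta.max()
                p = np.exp(eta)
                p /= p.sum()
                nb_p = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
                depth = int(rng.negative_binomial(cfg.depth_dispersion, nb_p))
                depth = max(depth, 500)
                counts = rng.multinomial(depth, p)
                sid = f"{study}_{comp[:4]}_{s:02d}"
                sample_ids.append(sid)
                count_rows.append(counts)
                meta_rows.append({
                    "study_id": study,
                    "compartment": comp,
                    "pair_id": f"{study}_pair{s:02d}",
                    "ecosystem": ecosystem,
                    "ph": round(study_ph, 3),
                    "latitude": round(study_lat, 3),
                })
        p_rhizo = _expected_compositions(base, deltas_j)
        p_bulk = _expected_compositions(base, np.zeros_like(deltas_j))
        v_rhizo = _expected_variables(p_rhizo, traits, taxonomy, fmap,
                                      edge_masses_fn, cfg.truth_depth)
        v_bulk = _expected_variables(p_bulk, traits, taxonomy, fmap,
                                     edge_masses_fn, cfg.truth_depth)
        truth_rows[study] = {
            var: math.log(v_rhizo[var] / v_bulk[var])
            if v_bulk[var] > 0 and v_rhizo[var] > 0 and not (
                math.isnan(v_rhizo[var]) or math.isnan(v_bulk[var]))
            else float("nan")
            for var in v_rhizo
        }

    counts = pd.DataFrame(np.vstack(count_rows), index=pd.Index(sample_ids, name="sample_id"),
                          columns=taxa)
    metadata = pd.DataFrame(meta_rows, index=pd.Index(sample_ids, name="sample_id"))
    truth = GroundTruth(
        effects=effects_s,
        tau2=cfg.tau2,
        blocks=pd.Series(blocks, index=taxa, name="block"),
        study_lnrr=pd.DataFrame.from_dict(truth_rows, orient="index").sort_index(),
        min_effect=cfg.effect_low if n_diff else 0.0,
    )
    return StudySet(counts=counts, metadata=metadata, taxonomy=taxonomy, tree=tree,
                    traits=traits, function_map=fmap, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture(dir_path: str | Path, bundle: StudySet) -> dict:
    """Write every artifact of a generated bundle as plain text; return a manifest."""
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "counts": "counts.tsv",
        "metadata": "metadata.tsv",
        "taxonomy": "taxonomy.tsv",
        "tree": "tree.nwk",
        "traits": "traits.tsv",
        "function_map": "functions.txt",
        "ground_truth": "ground_truth.json",
    }
    rio.write_count_table(bundle.counts, out / files["counts"])
    rio.write_metadata(bundle.metadata, out / files["metadata"])
    rio.write_taxonomy(bundle.taxonomy, out / files["taxonomy"])
    rio.write_tree(bundle.tree, out / files["tree"])
    rio.write_traits(bundle.traits, out / files["traits"])
    rio.write_function_map(bundle.function_map, out / files["function_map"])
    (out / files["ground_truth"]).write_text(bundle.truth.to_json(), encoding="utf-8")
    manifest = {
        "seed": bundle.config.seed,
        "config": dataclasses.asdict(bundle.config),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return manifest


def read_fixture(dir_path: str | Path) -> StudySet:
    """Load a bundle previously written by :func:`write_fixture`."""
    out = Path(dir_path)
    manifest = json.loads((out / "manifest.json").read_text(encoding="utf-8"))
    files = manifest["files"]
    cfg = SynthConfig(**manifest["config"])
    return StudySet(
        counts=rio.read_count_table(out / files["counts"]),
        metadata=rio.read_metadata(out / files["metadata"]),
        taxonomy=rio.read_taxonomy(out / files["taxonomy"]),
        tree=rio.read_tree(out / files["tree"]),
        traits=rio.read_traits(out / files["traits"]),
        function_map=rio.read_function_map(out / files["function_map"]),
        truth=GroundTruth.from_json(
            (out / files["ground_truth"]).read_text(encoding="utf-8")),
        config=cfg,
    )


# ---------------------------------------------------------------------------
# effect-level simulator (meta-analysis calibration)
# ---------------------------------------------------------------------------

def simulate_group_values(true_lnrr: float, tau2: float, n_studies: int,
                          n_per_group: int, cv: float, seed: int,
                          baseline_mean: float = 100.0,
                          baseline_sigma: float = 0.3):
    """Per-study paired group values whose true log response ratio is known.

    Study j has control mean ``m_j`` (log-normal around ``baseline_mean``) and
    treatment mean ``m_j * exp(theta_j)`` with ``theta_j ~ N(true_lnrr, tau2)``;
    individual sample values are normal with coefficient of variation ``cv``.
    Used to calibrate the random-effects pooling independently of the full
    community generator.

    Returns a list of ``(study_id, treatment_values, control_values)``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_studies):
        m_c = baseline_mean * rng.lognormal(0.0, baseline_sigma)
        theta = rng.normal(true_lnrr, math.sqrt(tau2)) if tau2 > 0 else true_lnrr
        m_t = m_c * math.exp(theta)
        treat = rng.normal(m_t, cv * m_t, size=n_per_group)
        ctrl = rng.normal(m_c, cv * m_c, size=n_per_group)
        out.append((f"study{j:02d}", np.abs(treat), np.abs(ctrl)))
    return out
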