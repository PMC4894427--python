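"""Synthetic three-species metabolomics study generator.

Emulates the structure of a comparative liver-metabolomics design: three
primate species (human, chimpanzee, rhesus), a handful of individuals per
species, technical replicates per individual, a KEGG-style tripartite
compound-reaction-enzyme network with pathway groupings, and matched
enzyme gene-expression data from the same individuals.

Generative model (log2 scale), for metabolite m measured on individual i,
replicate j::

    y[m, i, j] = mu_m + beta[m, species(i)] + u[m, i]
                 + c * sigma_ind * sum_r f[r, i] / sqrt(deg_m)
                 + batch_effect * v_m * s[batch(j)] + eps[m, i, j]

with individual effects ``u ~ N(0, (1 - c^2) * sigma_ind^2)`` for
network-annotated metabolites (``N(0, sigma_ind^2)`` otherwise),
replicate noise ``eps ~ N(0, sigma_rep^2)``, and per-reaction,
per-individual latent factors ``f ~ N(0, 1)`` shared by a reaction's
compounds. The ``c``-weighting keeps the total individual-level variance
at ``sigma_ind^2`` while giving two degree-1 compounds that share a
reaction a within-species correlation of ``c^2``.

Species effects ``beta`` are lineage-specific: a planted metabolite has
one species shifted by ``+-species_effect_size``, so it is differentially
concentrated (DC) for the two pairs involving that species and null for
the third. Enzyme-driven metabolites instead inherit a human-lineage
shift whose sign matches their driver enzyme's planted expression shift.
Planted outlier replicates receive additional heavy noise across all
metabolites, the artifact that quality control is expected to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import AbundanceMatrix, ReactionNetwork, SampleTable, SPECIES

__all__ = ["SimConfig", "TruthTable", "SimData", "simulate", "make_network",
            "null_config"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study; the seed fully determines output."""

    n_metabolites: int = 200
    n_individuals_per_species: int = 6
    n_replicates: int = 3
    fraction_dc_per_pair: float = 0.15
    species_effect_size: float = 2.0     # log2 units
    sigma_individual: float = 0.3
    sigma_replicate: float = 0.2
    n_reactions: int = 200
    mean_compounds_per_reaction: float = 3.0
    reaction_coupling_strength: float = 0.8
    fraction_enzyme_driven: float = 0.10
    enzyme_effect_size: float = 1.5
    batch_effect_size: float = 0.5
    n_outlier_replicates: int = 3
    seed: int = 0
    # secondary knobs
    baseline_mean: float = 10.0
    baseline_sd: float = 2.0
    expression_sigma: float = 0.25
    expression_effect_size: float = 1.5
    degree_tail_prob: float = 0.03

    n_species: int = 3  # fixed

    def validate(self):
        counts = [self.n_metabolites, self.n_individuals_per_species,
                  self.n_replicates, self.n_reactions]
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be positive")
        if not 0.0 <= self.reaction_coupling_strength <= 1.0:
            raise ConfigError("reaction_coupling_strength must be in [0, 1]")
        if self.mean_compounds_per_reaction > self.n_metabolites:
            raise ConfigError(
                "mean_compounds_per_reaction exceeds n_metabolites")
        if self.n_species != 3:
            raise ConfigError("the design is fixed at three species")


def null_config(**overrides) -> SimConfig:
    """A configuration with no planted structure of any kind."""
    cfg = SimConfig(fraction_dc_per_pair=0.0, species_effect_size=0.0,
                    reaction_coupling_strength=0.0,
                    fraction_enzyme_driven=0.0, batch_effect_size=0.0,
                    n_outlier_replicates=0)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class TruthTable:
    """Ground truth of the planted structure, for parameter recovery."""

    metabolites: pd.DataFrame
    """Per metabolite: mu_human/mu_chimpanzee/mu_rhesus (true log2 means),
    dc_HC/dc_HR/dc_CR flags, human_specific flag, annotated flag,
    enzyme_driven flag."""

    enzymes: pd.DataFrame
    """Per enzyme gene: de_HC/de_HR/de_CR flags, expression_shift,
    driven_metabolites (comma-joined ids)."""

    outlier_measurements: list
    batch_of_measurement: dict

    def dc_ids(self, pair: str) -> set:
        col = f"dc_{pair}"
        return set(self.metabolites.index[self.metabolites[col]])

    @property
    def human_specific_ids(self) -> set:
        return set(self.metabolites.index[self.metabolites["human_specific"]])


@dataclass
class SimData:
    """Bundle of all simulated inputs plus the ground truth."""

    abundance: AbundanceMatrix
    samples: SampleTable
    network: ReactionNetwork
    expression: pd.DataFrame          # genes x individuals (log2)
    expression_species: pd.Series     # species of each individual column
    truth: TruthTable
    config: SimConfig

    def write(self, out_dir):
        import os
        from . import io as mio
        os.makedirs(out_dir, exist_ok=True)
        mio.write_abundance(self.abundance, f"{out_dir}/abundance.tsv")
        mio.write_samples(self.samples, f"{out_dir}/samples.tsv")
        mio.write_network(self.network, out_dir)
        self.expression.to_csv(f"{out_dir}/expression.tsv", sep="\t",
                               index_label="gene_id", float_format="%.12g")
        pd.DataFrame({"individual": self.expression.columns,
                      "species": self.expression_species.values}).to_csv(
            f"{out_dir}/expression_individuals.tsv", sep="\t", index=False)
        self.truth.metabolites.to_csv(f"{out_dir}/truth_metabolites.tsv",
                                      sep="\t", index_label="metabolite_id",
                                      float_format="%.12g")
        self.truth.enzymes.to_csv(f"{out_dir}/truth_enzymes.tsv", sep="\t",
                                  index_label="gene_id",
                                  float_format="%.12g")


# ---------------------------------------------------------------------------
# network generator
# ---------------------------------------------------------------------------

def make_network(config: SimConfig, rng=None,
                 metabolite_ids=None) -> ReactionNetwork:
    """Draw a tripartite reaction network with a heavy-tailed degree law.

    Compound degrees follow a geometric body (most compounds in fewer than
    ten reactions) plus a small high-degree tail crossing the 20-reaction
    connectivity cutoff. Each reaction is catalyzed by at least one enzyme
    gene; pathways are unions of the compound sets of a few reactions.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if metabolite_ids is None:
        metabolite_ids = [f"C{i:04d}" for i in range(config.n_metabolites)]

    n_rx = config.n_reactions
    reactions = [f"R{i:04d}" for i in range(n_rx)]
    budget = int(round(n_rx * config.mean_compounds_per_reaction))

    compound_reaction = set()
    total = 0
    order = list(rng.permutation(metabolite_ids))
    for cid in order:
        if total >= budget:
            break
        if rng.random() < config.degree_tail_prob and n_rx > 21:
            deg = 21 + rng.geometric(0.2)
        else:
            deg = rng.geometric(1.0 / 1.7)
        deg = int(min(deg, n_rx))
        for r in rng.choice(n_rx, size=deg, replace=False):
            compound_reaction.add((cid, reactions[r]))
        total += deg
    # every reaction hosts at least one compound
    covered = {r for _, r in compound_reaction}
    used = sorted({c for c, _ in compound_reaction}) or [order[0]]
    for r in reactions:
        if r not in covered:
            compound_reaction.add((str(rng.choice(used)), r))

    n_enzymes = max(3, int(round(0.9 * n_rx)))
    enzymes = [f"G{i:04d}" for i in range(n_enzymes)]
    reaction_enzyme = set()
    for r in reactions:
        k = 1 + int(rng.random() < 0.15)
        for e in rng.choice(n_enzymes, size=min(k, n_enzymes),
                            replace=False):
            reaction_enzyme.add((r, enzymes[e]))

    n_pw = max(3, n_rx // 5)
    compound_pathway = set()
    by_reaction = {}
    for c, r in compound_reaction:
        by_reaction.setdefault(r, set()).add(c)
    for p in range(n_pw):
        k = int(rng.integers(2, 7))
        members = set()
        for r in rng.choice(n_rx, size=min(k, n_rx), replace=False):
            members |= by_reaction.get(reactions[r], set())
        for c in members:
            compound_pathway.add((c, f"P{p:03d}"))

    return ReactionNetwork(compound_reaction=compound_reaction,
                           reaction_enzyme=reaction_enzyme,
                           compound_pathway=compound_pathway)


# ---------------------------------------------------------------------------
# main simulator
# ---------------------------------------------------------------------------

def _plant_species_effects(cfg, rng, met_ids):
    """Lineage-specific shifts: round(f*n/2) metabolites per species, so
    each species pair carries ~f*n planted differences."""
    n = len(met_ids)
    per_lineage = int(round(cfg.fraction_dc_per_pair * n / 2.0))
    beta = pd.DataFrame(0.0, index=met_ids, columns=list(SPECIES))
    if cfg.fraction_dc_per_pair * n < 1 or cfg.species_effect_size == 0:
        if 0 < cfg.fraction_dc_per_pair * n < 1:
            import warnings
            warnings.warn("fraction_dc_per_pair too small for one "
                          "metabolite; planting nothing", stacklevel=3)
        return beta
    chosen = rng.choice(n, size=min(3 * per_lineage, n), replace=False)
    for k, sp in enumerate(SPECIES):
        # alternate signs so shifts stay compositionally balanced and
        # normalization sees no net distribution shift per species
        for j, idx in enumerate(chosen[k * per_lineage:
                                       (k + 1) * per_lineage]):
            sign = 1.0 if j % 2 == 0 else -1.0
            beta.loc[met_ids[idx], sp] = sign * cfg.species_effect_size
    return beta


def simulate(config: SimConfig) -> SimData:
    """Generate all pipeline inputs plus the ground-truth table."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    met_ids = [f"C{i:04d}" for i in range(cfg.n_metabolites)]
    network = make_network(cfg, rng=rng, metabolite_ids=met_ids)
    annotated = sorted(set(met_ids) & network.compounds)

    n_ind = cfg.n_individuals_per_species
    individuals, species_of_ind = [], {}
    for sp, tag in zip(SPECIES, ("H", "C", "R")):
        for i in range(n_ind):
            ind = f"{tag}{i + 1:02d}"
            individuals.append(ind)
            species_of_ind[ind] = sp

    # planted species effects (lineage-specific) ---------------------------
    beta = _plant_species_effects(cfg, rng, met_ids)

    # enzyme-driven shifts: drivers get a human-lineage expression shift;
    # their reactions' compounds inherit a same-sign human shift
    enzymes = sorted(network.enzymes)
    n_drivers = int(round(cfg.fraction_enzyme_driven * len(enzymes)))
    expr_shift = pd.Series(0.0, index=enzymes)
    driven_of = {e: [] for e in enzymes}
    driven_flag = pd.Series(False, index=met_ids)
    if n_drivers > 0 and cfg.enzyme_effect_size != 0:
        drivers = list(rng.choice(enzymes, size=n_drivers, replace=False))
        for j, e in enumerate(drivers):
            sign = 1.0 if j % 2 == 0 else -1.0
            expr_shift[e] = sign * cfg.expression_effect_size
            for c in sorted(network.compounds_of_enzyme(e)):
                if c in beta.index and beta.loc[c].abs().sum() == 0 \
                        and not driven_flag[c]:
                    beta.loc[c, "human"] = sign * cfg.enzyme_effect_size
                    driven_flag[c] = True
                    driven_of[e].append(c)

    mu0 = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_metabolites)
    true_means = beta.add(mu0, axis=0)

    # measurement layout ---------------------------------------------------
    meas_ids, meas_ind, meas_rep = [], [], []
    for ind in individuals:
        for j in range(1, cfg.n_replicates + 1):
            meas_ids.append(f"{ind}_r{j}")
            meas_ind.append(ind)
            meas_rep.append(j)
    n_meas = len(meas_ids)
    ind_index = {ind: k for k, ind in enumerate(individuals)}

    # individual-level effects --------------------------------------------
    c = cfg.reaction_coupling_strength
    sig_i = cfg.sigma_individual
    u = rng.normal(0.0, sig_i, size=(cfg.n_metabolites, len(individuals)))
    reactions = sorted(network.reactions)
    f_latent = rng.normal(0.0, 1.0, size=(len(reactions), len(individuals)))
    rx_index = {r: k for k, r in enumerate(reactions)}
    coupled = np.zeros_like(u)
    ann_set = set(annotated)
    for mi, m in enumerate(met_ids):
        if m in ann_set and c > 0:
            rs = sorted(network.reactions_of(m))
            fsum = f_latent[[rx_index[r] for r in rs]].sum(axis=0)
            coupled[mi] = c * sig_i * fsum / np.sqrt(len(rs))
            u[mi] *= np.sqrt(max(0.0, 1.0 - c * c))
    ind_effect = u + coupled

    # batch: replicate index is the batch; rank-1 artifact direction ------
    batch_scores = np.arange(1, cfg.n_replicates + 1, dtype=float)
    batch_scores -= batch_scores.mean()
    # run-order drift touches every analyte, with varying susceptibility
    v = (np.where(rng.random(cfg.n_metabolites) < 0.5, -1.0, 1.0)
         * (0.4 + np.abs(rng.normal(0.0, 0.6, cfg.n_metabolites))))

    Y = np.empty((cfg.n_metabolites, n_meas))
    sp_cols = {sp: k for k, sp in enumerate(SPECIES)}
    tm = true_means.to_numpy()
    for k, (ind, rep) in enumerate(zip(meas_ind, meas_rep)):
        sp = species_of_ind[ind]
        Y[:, k] = (tm[:, sp_cols[sp]]
                   + ind_effect[:, ind_index[ind]]
                   + cfg.batch_effect_size * v * batch_scores[rep - 1]
                   + rng.normal(0.0, cfg.sigma_replicate,
                                cfg.n_metabolites))

    # planted outlier replicates: at most one per individual --------------
    outlier_ids = []
    if cfg.n_outlier_replicates > 0:
        cand_inds = rng.choice(individuals,
                               size=min(cfg.n_outlier_replicates,
                                        len(individuals)),
                               replace=False)
        for ind in cand_inds:
            rep = int(rng.integers(1, cfg.n_replicates + 1))
            mid = f"{ind}_r{rep}"
            k = meas_ids.index(mid)
            Y[:, k] += rng.normal(0.0, 10.0 * cfg.sigma_replicate,
                                  cfg.n_metabolites)
            outlier_ids.append(mid)

    abundance = AbundanceMatrix(
        pd.DataFrame(Y, index=met_ids, columns=meas_ids)).canonical()
    samples = SampleTable(pd.DataFrame({
        "species": [species_of_ind[i] for i in meas_ind],
        "individual": meas_ind,
        "replicate": meas_rep,
        "batch": [f"batch{r}" for r in meas_rep],
        "sex": [("F" if ind_index[i] % 2 else "M") for i in meas_ind],
    }, index=pd.Index(meas_ids, name="measurement_id"))).canonical()

    # expression: genes x 18 individuals, human shift for drivers ---------
    expr_mu = rng.normal(6.0, 1.0, len(enzymes))
    X = np.empty((len(enzymes), len(individuals)))
    for k, ind in enumerate(individuals):
        shift = expr_shift.to_numpy() * (species_of_ind[ind] == "human")
        X[:, k] = expr_mu + shift + rng.normal(0.0, cfg.expression_sigma,
                                               len(enzymes))
    expression = pd.DataFrame(X, index=enzymes, columns=individuals)
    expression_species = pd.Series([species_of_ind[i] for i in individuals],
                                   index=individuals)

    # ground truth ---------------------------------------------------------
    tiny = 1e-9
    mm = true_means
    truth_met = pd.DataFrame({
        "mu_human": mm["human"], "mu_chimpanzee": mm["chimpanzee"],
        "mu_rhesus": mm["rhesus"],
        "dc_HC": (mm["human"] - mm["chimpanzee"]).abs() > tiny,
        "dc_HR": (mm["human"] - mm["rhesus"]).abs() > tiny,
        "dc_CR": (mm["chimpanzee"] - mm["rhesus"]).abs() > tiny,
        "annotated": [m in ann_set for m in met_ids],
        "enzyme_driven": driven_flag,
    }, index=pd.Index(met_ids, name="metabolite_id"))
    truth_met["human_specific"] = (truth_met["dc_HC"] & truth_met["dc_HR"]
                                   & ~truth_met["dc_CR"])
    truth_enz = pd.DataFrame({
        "expression_shift": expr_shift,
        "de_HC": expr_shift.abs() > tiny,
        "de_HR": expr_shift.abs() > tiny,
        "de_CR": False,
        "driven_metabolites": [",".join(driven_of[e]) for e in enzymes],
    }, index=pd.Index(enzymes, name="gene_id"))

    truth = TruthTable(
        metabolites=truth_met, enzymes=truth_enz,
        outlier_measurements=sorted(outlier_ids),
        batch_of_measurement=dict(zip(meas_ids,
                                      (f"batch{r}" for r in meas_rep))))
    return SimData(abundance=abundance, samples=samples, network=network,
                   expression=expression,
                   expression_species=expression_species,
                   truth=truth, config=cfg)
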