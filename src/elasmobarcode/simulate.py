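"""Synthetic barcode studies with known truth.

The generator emulates the statistical structure a barcode survey relies
on: an ultrametric taxonomy tree whose between-taxon path lengths equal
configured per-rank divergences, sequences evolved along it under the
two-parameter (kappa) substitution process -- so the K2P estimator is
unbiased for path length -- and planted identification events:

* ``misidentified`` -- the reported (field) species differs from the truth;
* ``novel`` -- a lineage with no conspecific reference sequence;
* ``cryptic`` -- one sample replaced by a divergent conspecific haplotype
  at a deep (3.5--5%) realized K2P distance from its references, planted
  by exact substitution counts so the realized divergence is controlled;
* ``ambiguous`` -- a second reference species nearly identical to the
  first, so database matches tie across species.

No indels are simulated; the sequences come out aligned by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BarcodeSequence, ReferenceRecord, write_sequences
from .taxonomy import BATOIDEA, ELASMOBRANCHII, HOLOCEPHALI, SELACHII, Lineage
from .tree import TreeNode

_DEFAULT_DIVERGENCES = {
    "intraspecific": 0.005,
    "interspecific": 0.05,
    "inter_genus": 0.10,
    "inter_family": 0.15,
    "inter_order": 0.20,
    "inter_infraclass": 0.25,
    "inter_class": 0.30,
}


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Shape and rates of a synthetic barcode study.

    The taxonomy is balanced: ``n_orders`` per infraclass (sharks and
    batoids), ``n_families`` per order, and so on, plus one chimaera-like
    outgroup species in a second class.  ``divergences`` are expected K2P
    path lengths between individuals whose lineages differ at each rank;
    they must increase strictly with rank.  ``kappa`` is the
    transition/transversion rate ratio.  Event rates are fractions of
    species (novel, cryptic, ambiguous) or of samples (misidentified).
    """

    n_orders: int = 2
    n_families: int = 2
    n_genera: int = 2
    n_species: int = 2
    n_samples: int = 3
    n_refs: int = 2
    seq_length: int = 654
    kappa: float = 4.0
    divergences: dict = field(
        default_factory=lambda: dict(_DEFAULT_DIVERGENCES))
    misidentified_rate: float = 0.05
    novel_rate: float = 0.06
    cryptic_rate: float = 0.06
    ambiguous_rate: float = 0.06
    cryptic_range: tuple = (0.036, 0.044)

    def __post_init__(self):
        order = ["intraspecific", "interspecific", "inter_genus",
                 "inter_family", "inter_order", "inter_infraclass",
                 "inter_class"]
        vals = [self.divergences[k] for k in order]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ConfigError(
                "per-rank divergences must increase strictly with rank")
        for r in (self.misidentified_rate, self.novel_rate,
                  self.cryptic_rate, self.ambiguous_rate):
            if not 0.0 <= r <= 1.0:
                raise ConfigError("event rates must lie in [0, 1]")
        if self.seq_length < 100:
            raise ConfigError("seq_length must be >= 100")


@dataclass
class TruthRecord:
    sample: str
    true_species: str
    reported_species: str
    event: str  # none | misidentified | novel | cryptic | ambiguous


@dataclass
class SyntheticStudy:
    queries: list[BarcodeSequence]
    references: list[ReferenceRecord]
    lineages: dict[str, Lineage]
    truth: list[TruthRecord]
    tree: TreeNode


def simulate_taxonomy_tree(
    cfg: SimConfig, seed: int = 0
) -> tuple[TreeNode, dict[str, Lineage]]:
    """Ultrametric species tree realizing the configured divergences.

    Node heights above the leaves are half the divergence of the rank the
    node separates, so any two species' path length equals the divergence
    of the most specific rank at which their lineages differ.
    """
    d = cfg.divergences
    h = {k: v / 2.0 for k, v in d.items()}
    lineages: dict[str, Lineage] = {}

    def leaf(name, height):
        node = TreeNode(name=name)
        node.length = height
        return node

    def join(children, parent_height, child_height):
        node = TreeNode(children=children)
        node.length = parent_height - child_height
        return node

    gid = 0
    infraclass_nodes = []
    for infra in (SELACHII, BATOIDEA):
        order_nodes = []
        for o in range(cfg.n_orders):
            order_name = f"{infra[:3]}iformes{o + 1}"
            family_nodes = []
            for f in range(cfg.n_families):
                family_name = f"{infra[:3]}idae{o + 1}{f + 1}"
                genus_nodes = []
                for g in range(cfg.n_genera):
                    gid += 1
                    genus = f"Genus{gid:03d}"
                    species_nodes = []
                    for s in range(cfg.n_species):
                        sp = f"{genus} ep{s + 1}"
                        lineages[sp] = Lineage(
                            species=sp, genus=genus, family=family_name,
                            order=order_name, infraclass=infra,
                            class_=ELASMOBRANCHII)
                        species_nodes.append(
                            leaf(sp, h["interspecific"]))
                    genus_nodes.append(join(
                        species_nodes, h["inter_genus"], h["interspecific"]))
                family_nodes.append(join(
                    genus_nodes, h["inter_family"], h["inter_genus"]))
            order_nodes.append(join(
                family_nodes, h["inter_order"], h["inter_family"]))
        infraclass_nodes.append(join(
            order_nodes, h["inter_infraclass"], h["inter_order"]))
    elasmo = join(
        infraclass_nodes, h["inter_class"], h["inter_infraclass"])
    out_sp = "Outgroupus phantasmus"
    lineages[out_sp] = Lineage(
        species=out_sp, genus="Outgroupus", family="Outgroupidae",
        order="Outgroupiformes", class_=HOLOCEPHALI)
    root = TreeNode(children=[elasmo, leaf(out_sp, h["inter_class"])])
    root.length = None
    return root, lineages


def evolve_sequences(
    tree: TreeNode, cfg: SimConfig, seed: int = 0
) -> list[BarcodeSequence]:
    """Evolve one sequence per leaf under the kappa-ratio process.

    Branch lengths are expected substitutions per site, so the expected
    pairwise K2P distance between two leaves equals their path length.
    The root sequence is uniform over {A, C, G, T}.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=cfg.seq_length, dtype=np.int64)
    out = []

    def walk(node, seq):
        if node.length:
            p_ts, p_tv = _k2p_site_probs(node.length, cfg.kappa)
            u = rng.random(cfg.seq_length)
            seq = seq.copy()
            ts = u < p_ts
            tv = (u >= p_ts) & (u < p_ts + p_tv)
            seq[ts] ^= 2  # A<->G, C<->T
            half = rng.random(cfg.seq_length) < 0.5
            seq[tv & half] ^= 1
            seq[tv & ~half] ^= 3
        if node.is_tip():
            letters = np.array(list("ACGT"))[seq]
            out.append(BarcodeSequence(
                id=node.name, seq="".join(letters)))
        else:
            for child in node.children:
                walk(child, seq)

    walk(tree, root_seq)
    return out


def _k2p_site_probs(t: float, kappa: float) -> tuple[float, float]:
    """Closed-form probabilities that a site shows a transition or a
    transversion difference across evolutionary distance ``t``."""
    alpha = kappa / (kappa + 2.0)  # transition rate under mu = 1
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-2.0 * (alpha + beta) * t)
    e2 = np.exp(-4.0 * beta * t)
    p_ts = 0.25 - 0.5 * e1 + 0.25 * e2
    p_tv = 0.5 - 0.5 * e2  # both transversion targets combined
    return p_ts, p_tv


def _plant_divergent_haplotype(
    name: str, ref: BarcodeSequence, d_target: float, cfg: SimConfig, rng
) -> BarcodeSequence:
    """Derive a deep conspecific haplotype from ``ref`` by exact counts.

    The transition/transversion difference counts expected at K2P distance
    ``d_target`` are applied to distinct random sites, so the realized
    distance to ``ref`` is controlled up to count rounding rather than
    left to substitution noise.
    """
    code = {c: i for i, c in enumerate("ACGT")}
    seq = np.array([code.get(c, 0) for c in ref.seq], dtype=np.int64)
    p_ts, p_tv = _k2p_site_probs(d_target, cfg.kappa)
    m_ts = round(p_ts * cfg.seq_length)
    m_tv = round(p_tv * cfg.seq_length)
    sites = rng.choice(cfg.seq_length, size=m_ts + m_tv, replace=False)
    seq[sites[:m_ts]] ^= 2
    tv_sites = sites[m_ts:]
    half = rng.random(m_tv) < 0.5
    seq[tv_sites[half]] ^= 1
    seq[tv_sites[~half]] ^= 3
    letters = np.array(list("ACGT"))[seq]
    return BarcodeSequence(id=name, seq="".join(letters))


def _attach_individuals(
    species_tree: TreeNode, cfg: SimConfig, novel: set, ambiguous: dict,
) -> TreeNode:
    """Expand species leaves into per-individual leaves.

    Each species leaf becomes a clade of query samples plus reference
    individuals diverging at the intraspecific depth; an ambiguous species
    gains reference individuals under a pseudo-sister label.
    """
    h_intra = cfg.divergences["intraspecific"] / 2.0
    tree = species_tree.copy()
    for tip in list(tree.tips()):
        sp = tip.name
        tag = sp.replace(" ", "_")  # FASTA ids must be whitespace-free
        stem = tip.length  # height of the parent node above the leaves
        n_q = cfg.n_samples if sp != "Outgroupus phantasmus" else 2
        individuals = [f"{tag}|q{s + 1}" for s in range(n_q)]
        if sp not in novel:
            individuals += [f"{tag}|ref{r + 1}" for r in range(cfg.n_refs)]
        if sp in ambiguous:
            individuals.append(f"{ambiguous[sp].replace(' ', '_')}|ref1")
        shallow = []
        for name in individuals:
            node = TreeNode(name=name)
            node.length = h_intra
            shallow.append(node)
        tip.name = None
        tip.extend(shallow)
        tip.length = stem - h_intra
    return tree


def generate_study(cfg: SimConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Build a full synthetic study: queries, references, lineages, truth."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    species_tree, lineages = simulate_taxonomy_tree(cfg, seed)
    all_species = [s for s in lineages if s != "Outgroupus phantasmus"]

    n_novel = round(cfg.novel_rate * len(all_species))
    n_cryptic = round(cfg.cryptic_rate * len(all_species))
    n_ambiguous = round(cfg.ambiguous_rate * len(all_species))
    chosen = rng.choice(
        len(all_species), size=n_novel + n_cryptic + n_ambiguous,
        replace=False)
    novel = {all_species[i] for i in chosen[:n_novel]}
    cryptic = {
        all_species[i]: float(rng.uniform(*cfg.cryptic_range))
        for i in chosen[n_novel:n_novel + n_cryptic]}
    ambiguous = {}
    for i in chosen[n_novel + n_cryptic:]:
        sp = all_species[i]
        twin = sp.rsplit(" ", 1)[0] + " epx"
        ambiguous[sp] = twin
        lin = lineages[sp]
        lineages[twin] = Lineage(
            species=twin, genus=lin.genus, family=lin.family,
            order=lin.order, infraclass=lin.infraclass, class_=lin.class_)

    sample_tree = _attach_individuals(species_tree, cfg, novel, ambiguous)
    seqs = {s.id: s for s in evolve_sequences(
        sample_tree, cfg, seed=int(rng.integers(0, 2**31 - 1)))}
    for sp, d_target in cryptic.items():
        tag = sp.replace(" ", "_")
        name = f"{tag}|q{cfg.n_samples}"
        seqs[name] = _plant_divergent_haplotype(
            seqs[name].id, seqs[f"{tag}|ref1"], d_target, cfg, rng)

    queries, references, truth = [], [], []
    ref_ok_species = [
        s for s in all_species
        if s not in novel and s not in cryptic and s not in ambiguous]
    acc = 0
    for name, seq in seqs.items():
        sp, tag = name.split("|")
        sp = sp.replace("_", " ")
        if tag.startswith("ref"):
            acc += 1
            accession = f"REF{acc:04d}"
            references.append(ReferenceRecord(
                accession=accession, label=sp, lineage=lineages[sp],
                seq=BarcodeSequence(id=accession, seq=seq.seq)))
        else:
            queries.append(BarcodeSequence(id=name, seq=seq.seq))
            if sp in novel:
                event, reported = "novel", sp
            elif sp in cryptic and tag == f"q{cfg.n_samples}":
                event, reported = "cryptic", sp
            elif sp in ambiguous:
                event, reported = "ambiguous", sp
            else:
                event, reported = "none", sp
            truth.append(TruthRecord(
                sample=name, true_species=sp, reported_species=reported,
                event=event))

    # field misidentifications: swap the reported label on a seeded draw
    for rec in truth:
        if rec.event != "none" or rec.true_species == "Outgroupus phantasmus":
            continue
        if rng.random() < cfg.misidentified_rate:
            others = [s for s in ref_ok_species if s != rec.true_species]
            rec.reported_species = others[int(rng.integers(len(others)))]
            rec.event = "misidentified"

    return SyntheticStudy(
        queries=queries, references=references, lineages=lineages,
        truth=truth, tree=sample_tree)


def study_lineage_map(study: SyntheticStudy) -> dict[str, Lineage]:
    """Sequence-id -> lineage map over a study's queries and references."""
    out = {}
    for t in study.truth:
        out[t.sample] = study.lineages[t.true_species]
    for r in study.references:
        out[r.accession] = r.lineage
    return out


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write queries.fasta, references.fasta, reference metadata and the
    truth table in the dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sequences(study.queries, outdir / "queries.fasta")
    write_sequences(
        [r.seq for r in study.references], outdir / "references.fasta")
    with open(outdir / "reference_meta.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["accession", "label", "species", "genus", "subfamily",
                    "family", "order", "infraclass", "class", "trusted"])
        for r in study.references:
            lin = r.lineage
            w.writerow([r.accession, r.label, lin.species, lin.genus,
                        "" if lin.subfamily == lin.family else lin.subfamily,
                        lin.family, lin.order, lin.infraclass, lin.class_,
                        int(r.trusted)])
    with open(outdir / "truth.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "true_species", "reported_species", "event"])
        for t in study.truth:
            w.writerow([t.sample, t.true_species, t.reported_species,
                        t.event])
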