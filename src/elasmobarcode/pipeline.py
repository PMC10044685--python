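"""End-to-end identification and gap-analysis runs plus report summaries.

Two execution modes mirror how the underlying evidence is available:

* **full** -- from sequences: rank each query against the reference
  library, classify the match, place the query on a midpoint-rooted NJ
  tree, and reconcile both approaches into a consensus identification;
* **tabulated** -- from an already-printed verification table: the
  match flags are recomputed from the printed best-match and percent
  columns (the full hit lists are not printed), and the summary counts
  are recomputed from the rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import gap as gap_mod
from .distances import DistanceMatrix, pairwise_matrix
from .identify import (
    CurationOverride,
    IdentifyConfig,
    MatchFlag,
    Status,
    apply_overrides,
    assign_match_flag,
    consensus_identify,
    flag_from_tabulated,
    rank_hits,
    tree_assign,
)
from .io import BarcodeSequence, ReferenceRecord, TabulatedMatchRecord
from .taxonomy import HOLOCEPHALI, SELACHII, Taxonomy, normalize_name
from .tree import TreeNode, midpoint_root, nj_tree


@dataclass
class PipelineConfig:
    identify: IdentifyConfig = dc_field(default_factory=IdentifyConfig)
    metric: str = "k2p"
    bootstrap_b: int = 1000
    seed: int = 0
    collapse_provisional: bool = False

    def __post_init__(self):
        if not 0.0 < self.identify.strong_pct < 100.0:
            raise ValueError("strong_pct must lie in (0, 100)")
        for t in (self.identify.t_conspecific, self.identify.t_cryptic):
            if not 0.0 < t < 1.0:
                raise ValueError("tree thresholds must lie in (0, 1)")


@dataclass
class IdentificationRow:
    sample: str
    location: str
    field_id: str
    best_match: str
    identity_pct: float
    flag: MatchFlag
    tree_match: str
    consensus: str
    status: Status | None
    notes: str = ""
    cryptic_split: bool = False


@dataclass
class IdentifyReport:
    rows: list[IdentificationRow]
    summary: dict
    tree: TreeNode | None = None


def run_identify(
    queries: list[BarcodeSequence],
    refs: list[ReferenceRecord],
    field_ids: dict[str, str],
    overrides: list[CurationOverride] | None = None,
    cfg: PipelineConfig | None = None,
    taxonomy: Taxonomy | None = None,
) -> IdentifyReport:
    """Full-mode identification of every query sequence.

    ``field_ids`` maps query id to the field identification under test.
    """
    cfg = cfg or PipelineConfig()
    overrides = overrides or []
    refs = apply_overrides(refs, overrides)
    library_species = {
        normalize_name(r.label, collapse=True) for r in refs}

    all_seqs = list(queries) + [r.seq for r in refs]
    dm = pairwise_matrix(all_seqs, metric="k2p")
    tree = midpoint_root(nj_tree(dm))

    rows = []
    for q in queries:
        field_id = field_ids[q.id]
        hits = rank_hits(q, refs, cfg=cfg.identify)
        flag = assign_match_flag(field_id, hits, cfg.identify)
        ta = tree_assign(q.id, tree, refs, dm, cfg.identify)
        result = consensus_identify(
            field_id, flag, hits, ta, overrides, library_species)
        rows.append(IdentificationRow(
            sample=q.id, location=q.location, field_id=field_id,
            best_match=hits[0].species, identity_pct=hits[0].identity_pct,
            flag=flag, tree_match=ta.species or "",
            consensus=result.final_name, status=result.status,
            notes=result.notes, cryptic_split=ta.cryptic_split))
    summary = summarize_rows(rows, taxonomy)
    return IdentifyReport(rows=rows, summary=summary, tree=tree)


def run_identify_tabulated(
    records: list[TabulatedMatchRecord],
    cfg: PipelineConfig | None = None,
    taxonomy: Taxonomy | None = None,
) -> IdentifyReport:
    """Tabulated-mode run: recompute flags and summaries from a printed
    verification table."""
    cfg = cfg or PipelineConfig()
    rows = []
    for rec in records:
        flag = flag_from_tabulated(rec, cfg.identify)
        rows.append(IdentificationRow(
            sample=rec.sample, location=rec.location,
            field_id=rec.field_id, best_match=rec.best_match,
            identity_pct=rec.ncbi_pct, flag=flag,
            tree_match=rec.tree_match, consensus=rec.consensus,
            status=None if not rec.consensus else (
                Status.INCONCLUSIVE if rec.inconclusive else (
                    Status.VERIFIED
                    if normalize_name(rec.consensus, collapse=True)
                    == normalize_name(rec.field_id, collapse=True)
                    else Status.REASSIGNED)),
        ))
    summary = summarize_rows(rows, taxonomy)
    return IdentifyReport(rows=rows, summary=summary)


def summarize_rows(
    rows: list[IdentificationRow], taxonomy: Taxonomy | None = None
) -> dict:
    """Aggregate counts over report rows.

    With a taxonomy, species tallies are split by infraclass (sharks =
    Selachii, batoids = Batoidea) and chimaeras (Holocephali) are
    reported separately; nominal counts collapse provisional ("cf.",
    numbered sp.) forms onto their nominal species.
    """
    flag_counts = {f.value: 0 for f in MatchFlag}
    status_counts = {s.value: 0 for s in Status}
    ls_pcts = []
    n_inconclusive = 0
    for r in rows:
        flag_counts[r.flag.value] += 1
        if r.flag is MatchFlag.LS:
            ls_pcts.append(r.identity_pct)
        if r.status is not None:
            status_counts[r.status.value] += 1
        if r.status in (Status.RETAINED, Status.INCONCLUSIVE):
            n_inconclusive += 1
    consensus = [r.consensus for r in rows if r.consensus]
    working = {normalize_name(c) for c in consensus}
    nominal = {normalize_name(c, collapse=True) for c in consensus}
    summary = {
        "n_samples": len(rows),
        "flag_counts": flag_counts,
        "status_counts": status_counts,
        "n_inconclusive": n_inconclusive,
        "ls_min_pct": min(ls_pcts) if ls_pcts else None,
        "ls_max_pct": max(ls_pcts) if ls_pcts else None,
        "n_species_working": len(working),
        "n_species_nominal": len(nominal),
    }
    if taxonomy is not None:
        by_infra: dict[str, set] = {}
        for name in nominal:
            lin = taxonomy.lookup(name)
            key = lin.infraclass or lin.class_
            by_infra.setdefault(key, set()).add(name)
        summary["n_species_by_infraclass"] = {
            k: len(v) for k, v in sorted(by_infra.items())}
        summary["n_species_nominal_elasmobranch"] = sum(
            len(v) for k, v in by_infra.items() if k != HOLOCEPHALI)
        field_sharks = {
            normalize_name(r.field_id, collapse=True)
            for r in rows
            if taxonomy.lookup(r.field_id).infraclass == SELACHII}
        summary["n_field_shark_species"] = len(field_sharks)
    return summary


def write_report(rows: list[IdentificationRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "location", "field_id", "best_match",
                    "identity_pct", "flag", "tree_match", "consensus",
                    "status", "notes"])
        for r in rows:
            w.writerow([
                r.sample, r.location, r.field_id, r.best_match,
                f"{r.identity_pct:.2f}", r.flag.value, r.tree_match,
                r.consensus, r.status.value if r.status else "", r.notes])


@dataclass
class GapReport:
    summaries: list[gap_mod.CategorySummary]
    anova: gap_mod.AnovaResult
    tukey: list[gap_mod.TukeyPair]
    labels: list[str]


def run_gap(
    dm: DistanceMatrix,
    lineages: dict,
    cfg: PipelineConfig | None = None,
) -> GapReport:
    """Inter-rank category summaries with ANOVA and Tukey HSD."""
    pools = gap_mod.categorized_distances(dm, lineages)
    cats = sorted(pools)
    summaries = gap_mod.category_summaries(dm, lineages)
    groups = [pools[c] for c in cats]
    anova = gap_mod.anova_oneway(groups)
    tukey = gap_mod.tukey_hsd(groups)
    return GapReport(
        summaries=summaries, anova=anova, tukey=tukey,
        labels=[c.label for c in cats])
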