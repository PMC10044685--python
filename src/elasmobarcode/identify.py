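"""Two-approach molecular species identification.

Approach one ranks a query against a local reference library by percent
identity (emulating a remote similarity search) and classifies the outcome
with one flag per query:

* ``OK`` -- strong match (>= ``strong_pct``) to the field identification only;
* ``DS`` -- strong best match to a *different* species;
* ``LS`` -- best match below the strong-match threshold (low similarity);
* ``MM`` -- two or more species tie within ``mm_window`` percentage points
  of the top identity (multiple-species match);
* ``MU`` -- the best-matching reference carries an indeterminate label
  ("sp." or "cf." forms; uncertain species).

Approach two places the query on a distance tree and reads off the smallest
clade that also contains reference material.  The two approaches are then
reconciled into a consensus identification whose status is one of
VERIFIED, REASSIGNED, RETAINED (field name kept, identity unresolved) or
INCONCLUSIVE (a "cf."-qualified working name).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .distances import DistanceMatrix, encode
from .io import BarcodeSequence, ReferenceRecord, TabulatedMatchRecord
from .taxonomy import is_provisional, normalize_name
from .tree import TreeNode

log = logging.getLogger(__name__)


class MatchFlag(str, Enum):
    OK = "OK"
    DS = "DS"  # different species
    LS = "LS"  # low similarity
    MM = "MM"  # multiple species
    MU = "MU"  # uncertain species


class Status(str, Enum):
    VERIFIED = "VERIFIED"
    REASSIGNED = "REASSIGNED"
    RETAINED = "RETAINED"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class Hit:
    reference: ReferenceRecord
    identity_pct: float

    @property
    def species(self) -> str:
        return self.reference.label


@dataclass
class TreeAssignment:
    species: str | None
    nearest_ref_distance: float
    cryptic_split: bool = False


@dataclass
class ConsensusResult:
    final_name: str
    status: Status
    flag: MatchFlag
    notes: str = ""

    @property
    def inconclusive(self) -> bool:
        return self.status in (Status.RETAINED, Status.INCONCLUSIVE)


@dataclass
class IdentifyConfig:
    """Decision thresholds.

    ``strong_pct`` is the strong-match identity bound in percent (matches
    at or above it are conclusive database hits); ``mm_window`` the
    percentage-point window within which a second species makes the match
    ambiguous; ``t_conspecific`` and ``t_cryptic`` are K2P proportions
    bounding conspecific clustering and deep (possibly cryptic)
    intraspecific splits.
    """

    strong_pct: float = 99.0
    mm_window: float = 0.5
    t_conspecific: float = 0.02
    t_cryptic: float = 0.05
    check_orientation: bool = False


@dataclass
class CurationOverride:
    """Declarative reference-library correction.

    ``kind`` is "rename" (the deposited label is updated before matching)
    or "retain" (morphology overrides a conflicting database match for the
    named sample; the field identification is kept, flagged unresolved).
    """

    target: str  # accession or label (rename) / sample id (retain)
    corrected_species: str
    reason: str = ""
    kind: str = "rename"


class ConfigurationError(ValueError):
    pass


# -- approach one: percent-identity search ---------------------------------

_aligner = PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 2
_aligner.mismatch_score = -3
_aligner.open_gap_score = -5
_aligner.extend_gap_score = -2
# free end gaps: identity is computed on the overlapping window only
try:
    _aligner.end_insertion_score = 0.0
    _aligner.end_deletion_score = 0.0
except AttributeError:  # older Biopython naming
    _aligner.target_end_gap_score = 0.0
    _aligner.query_end_gap_score = 0.0


def _identity_aligned(qa: np.ndarray, ra: np.ndarray) -> float:
    """Identity over jointly unambiguous columns of equal-length seqs."""
    valid = (qa < 4) & (ra < 4)
    n = int(valid.sum())
    if n == 0:
        return 0.0
    return 100.0 * float((valid & (qa == ra)).sum()) / n


def _identity_freealign(q: str, r: str) -> float:
    """End-gap-free global alignment identity (internal gaps count as
    differences, terminal-gap columns are excluded)."""
    aln = _aligner.align(q, r)[0]
    sa, sb = str(aln[0]), str(aln[1])
    start = max(len(sa) - len(sa.lstrip("-")), len(sb) - len(sb.lstrip("-")))
    end = len(sa) - max(
        len(sa) - len(sa.rstrip("-")), len(sb) - len(sb.rstrip("-")))
    matches = cols = 0
    for x, y in zip(sa[start:end], sb[start:end]):
        if x in "ACGT" and y in "ACGT":
            cols += 1
            matches += x == y
        elif x == "-" or y == "-":
            cols += 1  # internal gap column counts as a difference
    return 100.0 * matches / cols if cols else 0.0


def rank_hits(
    query: BarcodeSequence,
    library: list[ReferenceRecord],
    top_n: int = 20,
    cfg: IdentifyConfig | None = None,
) -> list[Hit]:
    """Rank references by percent identity to the query, best first.

    Equal-length pairs are compared column-wise (the sequences are
    same-locus fragments); unequal lengths fall back to an end-gap-free
    global alignment.  Ties are broken by accession.  With
    ``check_orientation`` the reverse complement is also tried and the
    better orientation kept.
    """
    if not library:
        raise ConfigurationError("reference library is empty")
    cfg = cfg or IdentifyConfig()
    qcodes = encode(query)
    variants = [(query.seq, qcodes)]
    if cfg.check_orientation:
        rc = str(Seq(query.seq).reverse_complement())
        variants.append((rc, encode(rc)))
    hits = []
    for ref in library:
        best = 0.0
        for qseq, qc in variants:
            if len(qseq) == len(ref.seq.seq):
                ident = _identity_aligned(qc, encode(ref.seq))
            else:
                ident = _identity_freealign(qseq, ref.seq.seq)
            best = max(best, ident)
        hits.append(Hit(reference=ref, identity_pct=best))
    hits.sort(key=lambda h: (-h.identity_pct, h.reference.accession))
    return hits[:top_n]


def assign_match_flag(
    field_id: str,
    hits: list[Hit],
    cfg: IdentifyConfig | None = None,
) -> MatchFlag:
    """Classify a ranked hit list against the field identification."""
    if not hits:
        raise ConfigurationError("flag assignment needs at least one hit")
    cfg = cfg or IdentifyConfig()
    top = hits[0]
    if top.identity_pct < cfg.strong_pct:
        return MatchFlag.LS
    if is_provisional(top.species):
        return MatchFlag.MU
    top_name = normalize_name(top.species, collapse=True)
    contenders = {
        normalize_name(h.species, collapse=True)
        for h in hits
        if h.identity_pct >= top.identity_pct - cfg.mm_window
    }
    if len(contenders) >= 2:
        return MatchFlag.MM
    if top_name != normalize_name(field_id, collapse=True):
        return MatchFlag.DS
    return MatchFlag.OK


def flag_from_tabulated(
    rec: TabulatedMatchRecord, cfg: IdentifyConfig | None = None
) -> MatchFlag:
    """Recompute the match flag from a printed report row.

    The printed rows store only the best match and its identity, not the
    full hit list, so the multi-species (MM) and uncertain-species (MU)
    conditions are taken from the row's annotation marker; low similarity
    is recomputed from the percentage and different-species from the name
    columns.  An ``R`` marker (revised reference identity) means the
    printed best match already carries the corrected name.
    """
    cfg = cfg or IdentifyConfig()
    if rec.ncbi_pct < cfg.strong_pct:
        return MatchFlag.LS
    if rec.marker == "MU" or is_provisional(rec.best_match):
        return MatchFlag.MU
    if rec.marker == "MM":
        return MatchFlag.MM
    best = normalize_name(rec.best_match.split("/")[0], collapse=True)
    if best != normalize_name(rec.field_id, collapse=True):
        return MatchFlag.DS
    return MatchFlag.OK


# -- approach two: tree placement ------------------------------------------


class UsageError(ValueError):
    pass


def tree_assign(
    query_id: str,
    tree: TreeNode,
    refs: list[ReferenceRecord],
    dm: DistanceMatrix,
    cfg: IdentifyConfig | None = None,
) -> TreeAssignment:
    """Read a species assignment off the smallest query+reference clade.

    Walking rootward from the query leaf, the first clade containing
    reference material determines the candidate species.  If that clade's
    references are a single species and the query's nearest-reference K2P
    distance is within ``t_conspecific``, the query is assigned to it;
    within ``t_cryptic`` it is assigned with ``cryptic_split`` raised (a
    deep intraspecific divergence); beyond that, or if the clade mixes
    species, no tree assignment is made.
    """
    cfg = cfg or IdentifyConfig()
    ref_species = {
        r.accession: normalize_name(r.label, collapse=True) for r in refs}
    try:
        leaf = tree.find(query_id)
    except Exception as err:
        raise UsageError(f"query {query_id!r} not in tree") from err

    node = leaf
    clade_refs: list[str] = []
    while node.parent is not None:
        node = node.parent
        clade_refs = [
            t.name for t in node.tips() if t.name in ref_species]
        if clade_refs:
            break
    if not clade_refs:
        return TreeAssignment(species=None, nearest_ref_distance=np.inf)

    dists = {acc: dm[query_id, acc] for acc in clade_refs}
    nearest_acc = min(dists, key=dists.get)
    d = dists[nearest_acc]
    species_in_clade = {ref_species[a] for a in clade_refs}
    if len(species_in_clade) > 1:
        return TreeAssignment(species=None, nearest_ref_distance=d)
    sp = ref_species[nearest_acc]
    if d <= cfg.t_conspecific:
        return TreeAssignment(species=sp, nearest_ref_distance=d)
    if d <= cfg.t_cryptic:
        return TreeAssignment(
            species=sp, nearest_ref_distance=d, cryptic_split=True)
    return TreeAssignment(species=None, nearest_ref_distance=d)


# -- consensus --------------------------------------------------------------


def _cf_form(name: str) -> str:
    """Qualify a binomial provisionally: 'Genus cf. epithet'."""
    name = normalize_name(name, collapse=True)
    parts = name.split(" ", 1)
    if len(parts) == 2 and "cf." not in parts[1]:
        return f"{parts[0]} cf. {parts[1]}"
    return name


def apply_overrides(
    refs: list[ReferenceRecord], overrides: list[CurationOverride]
) -> list[ReferenceRecord]:
    """Apply declarative label renames to a reference library."""
    renames = {
        o.target: o.corrected_species
        for o in overrides
        if o.kind == "rename"
    }
    out = []
    for r in refs:
        new_label = renames.get(r.accession, renames.get(r.label))
        if new_label is not None:
            log.warning(
                "reference %s relabelled %s -> %s",
                r.accession, r.label, new_label)
            r = ReferenceRecord(
                accession=r.accession, label=new_label, lineage=r.lineage,
                seq=r.seq, trusted=r.trusted)
        out.append(r)
    return out


def consensus_identify(
    field_id: str,
    flag: MatchFlag,
    hits: list[Hit],
    tree_result: TreeAssignment,
    overrides: list[CurationOverride] | None = None,
    library_species: set[str] | None = None,
) -> ConsensusResult:
    """Reconcile the database flag and the tree placement for one sample.

    ``library_species`` is the set of (collapsed) species names present in
    the reference library; it decides whether a low-similarity sample is a
    lineage with no conspecific reference (field name retained) or one
    that conflicts with existing references (treated as a "cf." form).
    """
    overrides = overrides or []
    field = normalize_name(field_id)
    field_nominal = normalize_name(field_id, collapse=True)
    tree_sp = tree_result.species
    retain = any(
        o.kind == "retain" and o.target == field_nominal for o in overrides)

    if flag is MatchFlag.OK:
        if tree_sp == field_nominal:
            note = ("deep intraspecific split; possible cryptic species"
                    if tree_result.cryptic_split else "")
            return ConsensusResult(field, Status.VERIFIED, flag, note)
        return ConsensusResult(
            field, Status.RETAINED, flag,
            "strong match but no corroborating tree clade")

    if flag is MatchFlag.DS:
        top = normalize_name(hits[0].species, collapse=True) if hits else ""
        if retain:
            return ConsensusResult(
                field, Status.RETAINED, flag,
                "morphology overrides conflicting database match")
        if top and tree_sp == top and top != field_nominal:
            return ConsensusResult(
                top, Status.REASSIGNED, flag,
                f"field misidentification corrected from {field}")
        return ConsensusResult(
            field, Status.RETAINED, flag,
            "conflicting match without tree corroboration")

    if flag is MatchFlag.LS:
        has_conspecific_ref = bool(
            library_species and field_nominal in library_species)
        if not has_conspecific_ref:
            return ConsensusResult(
                field, Status.RETAINED, flag,
                "no conspecific reference available; field name kept")
        return ConsensusResult(
            _cf_form(field), Status.INCONCLUSIVE, flag,
            "low similarity to available conspecific references")

    if flag is MatchFlag.MM:
        if tree_sp == field_nominal:
            return ConsensusResult(
                field, Status.VERIFIED, flag,
                "multiple database matches; likely misdeposited reference "
                "sequences")
        return ConsensusResult(
            field, Status.RETAINED, flag,
            "multiple-species match unresolved by the tree")

    # MU: indeterminate best match
    return ConsensusResult(
        _cf_form(field), Status.INCONCLUSIVE, flag,
        "best match carries an indeterminate label")
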