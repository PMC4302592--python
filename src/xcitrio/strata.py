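"""X-chromosome anchoring and evolutionary-stratum assignment.

A gene is anchored to the X when it has a 1:1 orthologue on the human
X conserved region (XCR) and/or the opossum X; a 1:1 orthologue
elsewhere on the human genome makes it autosomal; no 1:1 orthologue
leaves it unplaced and excluded from analysis.

Stratum assignment uses the flanking-gene rule on an ordered X gene map
labelled old/new: a locus that is itself a labelled map gene keeps its
own label; otherwise the nearest labelled genes on either side decide —
both old gives old, both new gives new, one of each excludes the locus,
and a missing or unknown flank leaves it unassigned.
"""

from __future__ import annotations

import logging
from typing import Optional

from .model import (
    HumanRegion,
    Locus,
    OrthologyRecord,
    Stratum,
    StratumAssignment,
    StratumCall,
    StratumGene,
    StratumMap,
    XLinkage,
)

logger = logging.getLogger(__name__)


def assign_x_linkage(
    gene_id: str, orthology: list[OrthologyRecord]
) -> XLinkage:
    """Anchor a gene via 1:1 orthology; unplaced genes are dropped upstream."""
    record = next((r for r in orthology if r.gene_id == gene_id), None)
    if record is None or not record.is_one_to_one:
        logger.info("gene %s has no 1:1 orthologue; unplaced", gene_id)
        return XLinkage.UNPLACED
    if record.human_chromosome_region == HumanRegion.XCR or record.opossum_chromosome == "X":
        return XLinkage.X
    if record.human_chromosome_region in (HumanRegion.X_OTHER, HumanRegion.AUTOSOME):
        return XLinkage.AUTOSOME
    if record.opossum_chromosome is not None:
        return XLinkage.AUTOSOME  # 1:1 orthologue on an opossum autosome
    logger.info("gene %s: 1:1 orthologue without chromosome placement", gene_id)
    return XLinkage.UNPLACED


def x_scaffolds_from_orthology(
    annotation_scaffolds: dict[str, list[str]], orthology: list[OrthologyRecord]
) -> set[str]:
    """Scaffolds carrying at least one X-anchored gene.

    *annotation_scaffolds* maps scaffold -> gene ids annotated on it.
    """
    out = set()
    for scaffold, gene_ids in annotation_scaffolds.items():
        if any(assign_x_linkage(g, orthology) == XLinkage.X for g in gene_ids):
            out.add(scaffold)
    return out


def _flanks(
    position: int, labelled: list[StratumGene]
) -> tuple[Optional[StratumGene], Optional[StratumGene]]:
    left = None
    right = None
    for gene in labelled:
        if gene.map_position < position:
            left = gene
        elif gene.map_position > position and right is None:
            right = gene
    return left, right


def assign_stratum(
    locus: Locus, stratum_map: StratumMap, map_position: Optional[int] = None
) -> StratumAssignment:
    """Apply self-label precedence then the flanking-gene rule.

    *map_position* overrides the locus's own position when the locus
    coordinate system differs from the map's; by default loci are assumed
    to carry positions on the map axis (e.g. a physical/linkage map of
    the X with scaffold offsets already applied).
    """
    if locus.gene_id is not None:
        own = stratum_map.get(locus.gene_id)
        if own is not None and own.stratum in (Stratum.OLD, Stratum.NEW):
            return StratumAssignment(locus.locus_id, StratumCall(own.stratum.value))
        if own is not None:
            position = own.map_position
        else:
            position = map_position if map_position is not None else locus.position
    else:
        position = map_position if map_position is not None else locus.position

    labelled = [g for g in stratum_map if g.stratum in (Stratum.OLD, Stratum.NEW)]
    left, right = _flanks(position, labelled)
    if left is None or right is None:
        return StratumAssignment(locus.locus_id, StratumCall.UNASSIGNED)
    if left.stratum == right.stratum:
        return StratumAssignment(locus.locus_id, StratumCall(left.stratum.value))
    return StratumAssignment(locus.locus_id, StratumCall.EXCLUDED)


def assign_strata(loci: list[Locus], stratum_map: StratumMap) -> list[StratumAssignment]:
    """Assign every locus, stamping ``locus.stratum`` in place."""
    assignments = []
    for locus in loci:
        assignment = assign_stratum(locus, stratum_map)
        locus.stratum = assignment.assignment
        assignments.append(assignment)
    return assignments
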