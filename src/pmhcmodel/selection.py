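"""Template selection: allele hierarchy plus anchor-driven peptide alignment
ranked with PAM30.

Candidates are gathered by walking the allele hierarchy — structures sharing
the target's exact protein name first, then its allele group, then its gene —
and the first non-empty tier is kept. Within that tier every template peptide
is aligned to the target with the anchor-position-driven construction: the
anchor positions are placed in matching columns, and length differences in
the binding core (the span between the first and last anchor) are absorbed by
gaps inserted at the exact centre of the mismatched core segment; flank
length differences become terminal gaps. The alignments are scored with the
PAM30 substitution matrix and the best-scoring template wins.

This is deliberately *not* an optimal-alignment search: the construction is
prescriptive, so anchors always stay in matched, ungapped columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

from .template_db import AlleleName, TemplateDatabase, TemplateEntry

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_GAP_OPEN = -9
DEFAULT_GAP_EXTEND = -1


class TemplateNotFoundError(Exception):
    """The database holds no template from the target's gene."""


@dataclass
class PeptideAlignment:
    """Anchor-driven pairwise peptide alignment.

    ``target_row`` and ``template_row`` are equal-length strings over the
    amino-acid alphabet plus ``'-'``; ``anchor_columns`` are the 0-based
    columns holding the paired anchors (never gapped in either row).
    """

    target_row: str
    template_row: str
    anchor_columns: tuple[int, ...]
    score: int | None = None

    def __post_init__(self):
        if len(self.target_row) != len(self.template_row):
            raise ValueError("alignment rows differ in length")

    @property
    def target_seq(self) -> str:
        return self.target_row.replace("-", "")

    @property
    def template_seq(self) -> str:
        return self.template_row.replace("-", "")


@lru_cache(maxsize=None)
def pam30_matrix():
    return substitution_matrices.load("PAM30")


def candidate_templates(
    db: TemplateDatabase, target_allele: AlleleName | str
) -> tuple[list[TemplateEntry], str | None]:
    """Compile the putative template list for an allele.

    Returns the first non-empty tier with its tag: ``"allele"`` (exact
    protein), ``"group"``, or ``"gene"``. An empty list with tag ``None``
    means the database has nothing from the target's gene.
    """
    if isinstance(target_allele, str):
        target_allele = AlleleName.parse(target_allele)
    parsed = [
        (entry, [AlleleName.parse(a) for a in entry.alleles]) for entry in db.entries
    ]
    tiers: list[tuple[str, callable]] = []
    if target_allele.protein:
        tiers.append(("allele", lambda a: a.protein == target_allele.protein))
    if target_allele.group:
        tiers.append(("group", lambda a: a.group == target_allele.group))
    tiers.append(("gene", lambda a: a.gene == target_allele.gene))
    for tag, pred in tiers:
        hits = [entry for entry, names in parsed if any(pred(a) for a in names)]
        if hits:
            return hits, tag
    return [], None


def _pad_centre(chars: list[str], n_gaps: int) -> list[str]:
    """Insert a contiguous gap block at the centre of a core segment: after
    the first floor(n/2) characters, i.e. an odd surplus sits immediately
    left of centre."""
    cut = len(chars) // 2
    return chars[:cut] + ["-"] * n_gaps + chars[cut:]


def anchor_align(
    target_seq: str,
    target_anchors,
    template_seq: str,
    template_anchors,
) -> PeptideAlignment:
    """Anchor-position-driven alignment of target and template peptides.

    Anchors (1-based, equal cardinality >= 2) are paired in ascending order
    and forced into shared columns. Core-segment length mismatches get centre
    gaps in the shorter row; flank mismatches get terminal gaps.
    """
    ta = sorted(set(target_anchors))
    sa = sorted(set(template_anchors))
    if len(ta) != len(sa):
        raise ValueError(f"anchor cardinality mismatch: {ta} vs {sa}")
    if len(ta) < 2:
        raise ValueError("need at least two anchors")
    for seq, anchors, label in ((target_seq, ta, "target"), (template_seq, sa, "template")):
        if any(not 1 <= a <= len(seq) for a in anchors):
            raise ValueError(f"{label} anchors {anchors} out of range for {len(seq)}-mer")

    t_row: list[str] = []
    s_row: list[str] = []
    anchor_cols: list[int] = []

    # left flank (terminal gaps pad the shorter flank on the far left)
    t_fl = list(target_seq[: ta[0] - 1])
    s_fl = list(template_seq[: sa[0] - 1])
    width = max(len(t_fl), len(s_fl))
    t_row += ["-"] * (width - len(t_fl)) + t_fl
    s_row += ["-"] * (width - len(s_fl)) + s_fl

    for k in range(len(ta)):
        anchor_cols.append(len(t_row))
        t_row.append(target_seq[ta[k] - 1])
        s_row.append(template_seq[sa[k] - 1])
        if k + 1 < len(ta):
            t_core = list(target_seq[ta[k] : ta[k + 1] - 1])
            s_core = list(template_seq[sa[k] : sa[k + 1] - 1])
            diff = len(t_core) - len(s_core)
            if diff > 0:
                s_core = _pad_centre(s_core, diff)
            elif diff < 0:
                t_core = _pad_centre(t_core, -diff)
            t_row += t_core
            s_row += s_core

    # right flank (terminal gaps on the far right)
    t_fr = list(target_seq[ta[-1] :])
    s_fr = list(template_seq[sa[-1] :])
    width = max(len(t_fr), len(s_fr))
    t_row += t_fr + ["-"] * (width - len(t_fr))
    s_row += s_fr + ["-"] * (width - len(s_fr))

    return PeptideAlignment(
        target_row="".join(t_row),
        template_row="".join(s_row),
        anchor_columns=tuple(anchor_cols),
    )


def _gap_penalty(row: str, gap_open: int, gap_extend: int) -> int:
    total = 0
    in_gap = False
    for ch in row:
        if ch == "-":
            total += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            in_gap = False
    return total


def score_alignment(
    alignment: PeptideAlignment,
    matrix=None,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> int:
    """PAM30 sum over aligned residue pairs plus affine gap penalties
    (``gap_open`` per gap run, ``gap_extend`` per additional gap column)."""
    if matrix is None:
        matrix = pam30_matrix()
    score = 0
    for a, b in zip(alignment.target_row, alignment.template_row):
        if a == "-" or b == "-":
            continue
        if a not in AMINO_ACIDS or b not in AMINO_ACIDS:
            raise ValueError(f"character outside amino-acid alphabet: {a!r}/{b!r}")
        score += int(matrix[a, b])
    score += _gap_penalty(alignment.target_row, gap_open, gap_extend)
    score += _gap_penalty(alignment.template_row, gap_open, gap_extend)
    return score


def select_template(
    db: TemplateDatabase,
    target,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> tuple[TemplateEntry, PeptideAlignment]:
    """Pick the best template for a modelling target.

    ``target`` needs ``peptide_seq``, ``anchors`` and ``allele`` attributes.
    Candidates come from :func:`candidate_templates`; the winner maximizes
    the PAM30 alignment score, with ties broken by better (lower) resolution
    and then lexicographically smallest ``source_id``.
    """
    allele = target.allele
    if isinstance(allele, str):
        allele = AlleleName.parse(allele)
    candidates, tier = candidate_templates(db, allele)
    if not candidates:
        raise TemplateNotFoundError(
            f"no template from gene {allele.gene!r} for target allele {allele.raw!r}"
        )
    target_anchors = sorted(target.anchors)
    scored = []
    for entry in candidates:
        entry_anchors = sorted(entry.anchors)
        if len(entry_anchors) != len(target_anchors):
            entry_anchors = [2, len(entry.peptide_seq)]
        aln = anchor_align(target.peptide_seq, target_anchors, entry.peptide_seq, entry_anchors)
        aln.score = score_alignment(aln, gap_open=gap_open, gap_extend=gap_extend)
        scored.append((entry, aln))
    logger.info(
        "template search tier=%s candidates=%s",
        tier,
        [(e.source_id, a.score) for e, a in scored],
    )
    best_entry, best_aln = min(
        scored,
        key=lambda ea: (
            -ea[1].score,
            ea[0].resolution if ea[0].resolution is not None else float("inf"),
            ea[0].source_id,
        ),
    )
    logger.info("selected template %s (tier %s, score %d)", best_entry.source_id, tier, best_aln.score)
    return best_entry, best_aln
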