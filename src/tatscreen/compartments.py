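"""Four-compartment assignment of paired PBMC/TIL repertoires.

Clones observed in both the blood and the tumour of one patient define the
shared compartments (PBMCs_Shared / TILs_Shared — same clonotypes, distinct
tissue of observation); clones seen in only one tissue fall in PBMCs_Only /
TILs_Only. The PBMCs_Shared cells are the circulating tumour-associated
T cells (cTATs) that the classifier downstream learns to recognise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import CloneKey, Repertoire, TcrPool

PBMCS_SHARED = "PBMCs_Shared"
PBMCS_ONLY = "PBMCs_Only"
TILS_SHARED = "TILs_Shared"
TILS_ONLY = "TILs_Only"


@dataclass
class CompartmentAssignment:
    subject_id: str
    #: (tissue, clone_key) -> compartment label
    labels: dict[tuple[str, CloneKey], str]
    shared_sequences: frozenset[str]
    match_on: str = "cdr3_aa"

    def keys_in(self, compartment: str) -> set[CloneKey]:
        return {key for (tissue, key), lab in self.labels.items() if lab == compartment}


@dataclass
class OverlapSummary:
    """Shared-TCR proportions at sequence level (unique CDR3s) and clone
    level (count-weighted). ``None`` marks a proportion undefined because
    the corresponding repertoire is empty."""

    subject_id: str
    pbmc_shared_prop_seq: float | None
    pbmc_shared_prop_clone: float | None
    til_shared_prop_seq: float | None
    til_shared_prop_clone: float | None


def assign_compartments(
    pbmc: Repertoire, til: Repertoire, match_on: str = "cdr3_aa"
) -> CompartmentAssignment:
    """Partition clones of a paired sample into the four sharing compartments.

    Sharing is an exact match on ``cdr3_aa`` (default; consistent with the
    pool/classifier stages) or on the full (V, CDR3, J) ``clone_key``.
    """
    if match_on not in ("cdr3_aa", "clone_key"):
        raise ValueError(f"match_on must be 'cdr3_aa' or 'clone_key', got {match_on!r}")
    if pbmc.subject_id != til.subject_id:
        raise ValueError(
            f"paired repertoires must share subject_id ({pbmc.subject_id!r} != {til.subject_id!r})"
        )

    if match_on == "cdr3_aa":
        shared = pbmc.unique_sequences & til.unique_sequences

        def is_shared(key: CloneKey) -> bool:
            return key[1] in shared

    else:
        shared_keys = set(pbmc.clones) & set(til.clones)
        shared = {k[1] for k in shared_keys}

        def is_shared(key: CloneKey) -> bool:
            return key in shared_keys

    labels: dict[tuple[str, CloneKey], str] = {}
    for key in pbmc.clones:
        labels[("PBMC", key)] = PBMCS_SHARED if is_shared(key) else PBMCS_ONLY
    for key in til.clones:
        labels[("TIL", key)] = TILS_SHARED if is_shared(key) else TILS_ONLY
    return CompartmentAssignment(
        subject_id=pbmc.subject_id,
        labels=labels,
        shared_sequences=frozenset(shared),
        match_on=match_on,
    )


def _props(rep: Repertoire, shared_keys: set[CloneKey]) -> tuple[float | None, float | None]:
    if len(rep) == 0:
        return None, None
    shared_seqs = {k[1] for k in shared_keys}
    seq_prop = len(shared_seqs & rep.unique_sequences) / len(rep.unique_sequences)
    shared_count = sum(c.count for k, c in rep.clones.items() if k in shared_keys)
    return seq_prop, shared_count / rep.total_count


def overlap_proportion(
    assignment: CompartmentAssignment, pbmc: Repertoire, til: Repertoire
) -> OverlapSummary:
    """Shared-TCR proportion per tissue at sequence and clone level."""
    pbmc_seq, pbmc_clone = _props(pbmc, assignment.keys_in(PBMCS_SHARED))
    til_seq, til_clone = _props(til, assignment.keys_in(TILS_SHARED))
    return OverlapSummary(
        subject_id=assignment.subject_id,
        pbmc_shared_prop_seq=pbmc_seq,
        pbmc_shared_prop_clone=pbmc_clone,
        til_shared_prop_seq=til_seq,
        til_shared_prop_clone=til_clone,
    )


def extract_tats(assignment: CompartmentAssignment, pbmc: Repertoire) -> Repertoire:
    """The PBMCs_Shared sub-repertoire: circulating tumour-associated T cells,
    with their PBMC counts preserved."""
    return pbmc.subset(assignment.keys_in(PBMCS_SHARED))


def pool_overlap(rep: Repertoire, pool: TcrPool) -> tuple[int, set[str]]:
    """Number (and identity) of distinct CDR3 sequences also present in a
    reference pool. This is the risk-score denominator."""
    overlapping = rep.unique_sequences & pool.sequences
    return len(overlapping), overlapping
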