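"""Proteome survey: CBM40 detection, sialidase co-occurrence, redundancy
reduction and taxon tabulation.

The survey mirrors the downstream analysis of a domain search: every
protein carrying at least one CBM40-type hit becomes a
:class:`SurveyRecord`; records are screened for a co-occurring sialidase
catalytic domain (GH33), reduced to a non-redundant representative set by
greedy identity clustering (default threshold 80%), and tabulated by
subtype and taxon at the representative level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .hmm import ProfileHmm, TypeCall, classify_hit, scan_sequence

# Asp-box motif (S-x-D-x-G-x-T-W) fallback screen for sialidase domains;
# off by default, the profile-HMM screen is authoritative.
import re

_ASP_BOX = re.compile(r"S.D.G.TW")


@dataclass
class SurveyRecord:
    sequence_id: str
    taxon: tuple[str, str, str]          # (phylum, class, genus)
    cbm40_calls: list[TypeCall]
    has_sialidase: bool
    protein_length: int
    label_override: str | None = None   # set when records are re-loaded from TSV

    @property
    def best_label(self) -> str:
        """Label of the highest-scoring non-rejected call (else 'reject')."""
        if self.label_override is not None:
            return self.label_override
        live = [c for c in self.cbm40_calls if c.label != "reject"]
        if not live:
            return "reject"
        return max(live, key=lambda c: c.hit.bit_score).label


@dataclass
class ClusterSet:
    clusters: list[tuple[str, list[str]]]  # (representative_id, member_ids)
    identity_threshold: float

    @property
    def representatives(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    def member_map(self) -> dict[str, str]:
        out = {}
        for rep, members in self.clusters:
            for m in members:
                out[m] = rep
        return out


_UNCLASSIFIED = ("unclassified", "unclassified", "unclassified")


def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """TSV with columns: sequence id, phylum, class, genus."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 4:
        raise ValueError("taxonomy table needs 4 columns: id, phylum, class, genus")
    return {
        str(r[0]): (str(r[1]), str(r[2]), str(r[3]))
        for r in df.itertuples(index=False)
    }


def survey_proteomes(
    proteins: list[tuple[str, str]],
    canonical_model: ProfileHmm,
    vibrio_model: ProfileHmm,
    gh33_model: ProfileHmm | None,
    decoy_models: list[ProfileHmm] | None = None,
    combined_model: ProfileHmm | None = None,
    taxonomy: dict[str, tuple[str, str, str]] | None = None,
    report_threshold_bits: float = 10.0,
    margin_bits: float = 0.0,
    aspbox_fallback: bool = False,
) -> list[SurveyRecord]:
    """Scan proteins for CBM40 domains and screen for GH33 co-occurrence.

    Detection uses the combined model when given (single search pass over
    both subtypes) plus the per-type models for score resolution;
    otherwise the two per-type models detect directly.  Returns one record
    per protein with at least one non-rejected CBM40 call, ordered by
    sequence id.
    """
    ids = [pid for pid, _ in proteins]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence ids: {dup}")
    decoys = decoy_models or []
    scan_models = [canonical_model, vibrio_model, *decoys]
    if combined_model is not None:
        scan_models = [combined_model, *scan_models]

    records: list[SurveyRecord] = []
    for pid, seq in sorted(proteins):
        hits = scan_sequence(
            scan_models, seq, pid, report_threshold_bits=report_threshold_bits
        )
        calls = [
            classify_hit(
                h,
                canonical_model,
                vibrio_model,
                list(decoys),
                margin_bits=margin_bits,
                report_threshold_bits=report_threshold_bits,
            )
            for h in hits
        ]
        calls = [c for c in calls if c.label != "reject"]
        if not calls:
            continue
        has_sialidase = False
        if gh33_model is not None:
            gh_hits = scan_sequence(
                [gh33_model], seq, pid, report_threshold_bits=report_threshold_bits
            )
            has_sialidase = len(gh_hits) > 0
        if not has_sialidase and aspbox_fallback:
            has_sialidase = len(_ASP_BOX.findall(seq)) >= 2
        taxon = (taxonomy or {}).get(pid, _UNCLASSIFIED)
        records.append(
            SurveyRecord(
                sequence_id=pid,
                taxon=taxon,
                cbm40_calls=calls,
                has_sialidase=has_sialidase,
                protein_length=len(seq),
            )
        )
    return records


def cooccurrence_fraction(records: list[SurveyRecord], label: str) -> float:
    """Fraction of records of a given subtype that also carry a sialidase."""
    sel = [r for r in records if r.best_label == label]
    if not sel:
        raise ValueError(f"empty class: no records labelled {label!r}")
    return sum(r.has_sialidase for r in sel) / len(sel)


_aligner: Align.PairwiseAligner | None = None


def _global_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _aligner = a
    return _aligner


def pairwise_identity(
    seq_a: str, seq_b: str, mode: str = "global_align"
) -> float:
    """Percent identity between two sequences.

    ``aligned_columns``: the inputs are rows of one alignment (equal
    length); identity = identical residue pairs / columns not gapped in
    both, with a gap against a residue counting as a mismatch.
    ``global_align``: a BLOSUM62 global alignment (gap open -11 / extend
    -1) is computed first and scored the same way.
    """
    if mode == "aligned_columns":
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned_columns mode requires equal lengths")
        pairs = [
            (a, b)
            for a, b in zip(seq_a.upper(), seq_b.upper())
            if not (a in "-." and b in "-.")
        ]
        if not pairs:
            raise ValueError("no comparable columns")
        ident = sum(a == b and a not in "-." for a, b in pairs)
        return 100.0 * ident / len(pairs)
    if mode == "global_align":
        aln = _global_aligner().align(seq_a.upper(), seq_b.upper())[0]
        a_row, b_row = str(aln[0]), str(aln[1])
        return pairwise_identity(a_row, b_row, mode="aligned_columns")
    raise ValueError(f"unknown identity mode {mode!r}")


def reduce_redundancy(
    sequences: list[tuple[str, str]],
    threshold: float = 0.80,
    mode: str = "global_align",
) -> ClusterSet:
    """Greedy incremental identity clustering.

    Sequences are visited by descending length (ties by id); each joins
    the first existing representative it matches at >= ``threshold``
    global identity, else founds a new cluster.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    order = sorted(sequences, key=lambda r: (-len(r[1]), r[0]))
    reps: list[tuple[str, str]] = []
    clusters: dict[str, list[str]] = {}
    for rid, seq in order:
        for rep_id, rep_seq in reps:
            if pairwise_identity(seq, rep_seq, mode=mode) >= 100.0 * threshold:
                clusters[rep_id].append(rid)
                break
        else:
            reps.append((rid, seq))
            clusters[rid] = [rid]
    return ClusterSet(
        clusters=[(rid, clusters[rid]) for rid, _ in reps],
        identity_threshold=threshold,
    )


def tabulate_taxa(
    records: list[SurveyRecord], clusters: ClusterSet
) -> pd.DataFrame:
    """Counts of cluster representatives by (subtype label, phylum, class,
    genus), plus distinct-genus counts per label.

    Returns a DataFrame with columns label, phylum, class, genus, count,
    in deterministic (sorted) row order.  Representatives without a survey
    record raise a ``KeyError``; records with unknown taxon are binned
    under ``unclassified``.
    """
    by_id = {r.sequence_id: r for r in records}
    rows = []
    for rep in clusters.representatives:
        if rep not in by_id:
            raise KeyError(f"cluster representative {rep!r} has no survey record")
        r = by_id[rep]
        phylum, cls, genus = r.taxon
        rows.append((r.best_label, phylum, cls, genus))
    df = pd.DataFrame(rows, columns=["label", "phylum", "class", "genus"])
    out = (
        df.groupby(["label", "phylum", "class", "genus"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out


def genus_counts(table: pd.DataFrame) -> pd.Series:
    """Distinct genera per subtype label from a `tabulate_taxa` table."""
    return table.groupby("label")["genus"].nunique().sort_index()
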