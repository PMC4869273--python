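"""Allele-level expression quantification.

After typing, each individual's reads are re-aligned at zero mismatches
against only the alleles called in that individual, read counts per allele
are determined, and proportions are normalised separately within the
classical and within the non-classical class — the within-class
read-proportion semantics of the method's expression tables.
"""

from __future__ import annotations

import pandas as pd

from .align import build_index
from .align import assign_reads
from .calling import _align_all
from .catalogue import CLASSICAL, NONCLASSICAL, AlleleCatalogue


def final_alignment_counts(
    reads,
    called_alleles,
    cat: AlleleCatalogue,
    policy: str = "fractional",
    seed: int = 0,
    k: int = 15,
) -> dict[str, float]:
    """Zero-mismatch counts against the individual's called alleles only.

    Multi-mapping reads are split fractionally by default (deterministic);
    ``random`` reproduces single-report behaviour under the seed.  Alleles
    with no reads keep an explicit 0 count.
    """
    called_alleles = list(called_alleles)
    if not called_alleles:
        raise ValueError("called allele set is empty")
    sub = cat.subset(called_alleles)
    index = build_index(sub, k)
    hits, lengths = _align_all(reads, index, 0, "all_valid")
    assignment = assign_reads(hits, lengths, policy=policy, seed=seed)
    return {a: assignment.counts.get(a, 0.0) for a in called_alleles}


def expression_proportions(
    counts: dict[str, float],
    cat: AlleleCatalogue,
    individual_id: str = "sample",
    length_normalized: bool = False,
) -> pd.DataFrame:
    """Within-class read proportions for one individual.

    Proportions are raw count ratios (class I allele lengths are nearly
    equal); a length-normalised mode divides counts by allele length first.
    A class whose total is zero gets missing (NaN) proportions rather than
    0/0.
    """
    rows = []
    for allele_id, raw in counts.items():
        allele = cat.get(allele_id)
        value = raw / len(allele) if length_normalized else raw
        rows.append(
            {
                "individual": individual_id,
                "allele_id": allele_id,
                "gene": allele.gene_label,
                "class_kind": allele.class_kind,
                "raw_count": raw,
                "_value": value,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["individual", "allele_id", "gene", "class_kind", "raw_count", "proportion"]
        )
    df["proportion"] = float("nan")
    for kind in (CLASSICAL, NONCLASSICAL):
        mask = df["class_kind"] == kind
        total = df.loc[mask, "_value"].sum()
        if total > 0:
            df.loc[mask, "proportion"] = df.loc[mask, "_value"] / total
    return df.drop(columns="_value").sort_values(
        ["class_kind", "gene", "allele_id"], ignore_index=True
    )


def cohort_expression_table(
    per_individual: dict[str, pd.DataFrame], class_kind: str
) -> pd.DataFrame:
    """Cohort layout: rows (gene, allele), one column per individual,
    cells = proportion at 3 decimals, blank when the allele is absent."""
    frames = []
    for individual, df in sorted(per_individual.items()):
        sel = df[df["class_kind"] == class_kind]
        frames.append(
            sel.set_index(["gene", "allele_id"])["proportion"].rename(individual)
        )
    if not frames:
        return pd.DataFrame()
    table = pd.concat(frames, axis=1).sort_index()
    return table.round(3)
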