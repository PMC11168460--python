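"""Targeted-MS (PRM) quantification of ubiquitylation sites.

Parallel reaction monitoring yields one intensity per peptide per sample.
Modified (GG-remnant) peptide intensities are made comparable across the
two samples of a pair (deubiquitylase wild type vs. catalytically dead
mutant) by dividing by the summed intensity of five unmodified reference
peptides of the same protein in the same sample; the readout is the log2
ratio of the normalized intensities.  For discovery (non-targeted) data,
ubiquitylation-site intensities are instead normalized by the parent
protein's intensity in the matching gel section.

Tables are long-format with columns ``peptide_id``, ``site``,
``modified``, ``sample_id``, ``pair_id``, ``condition``, ``intensity``.
Peptides mapping to the same site are kept as separate rows (a site
covered by two peptides contributes two data points); aggregation to site
level is an explicit option of :func:`log2_pair_ratios`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_prm_pair",
    "log2_pair_ratios",
    "normalize_site_by_gel_section",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "peptide_id", "site", "modified", "sample_id", "pair_id",
    "condition", "intensity",
)
N_REFERENCE_PEPTIDES = 5


def _check_table(records: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"PRM table is missing columns: {sorted(missing)}")
    if (records["intensity"] < 0).any() or not np.isfinite(
        records["intensity"]
    ).all():
        bad = records.loc[
            (records["intensity"] < 0) | ~np.isfinite(records["intensity"]),
            "peptide_id",
        ].tolist()
        raise ValueError(f"intensities must be finite and >= 0; bad: {bad}")
    dup = records.duplicated(["peptide_id", "sample_id"])
    if dup.any():
        pairs = records.loc[dup, ["peptide_id", "sample_id"]].values.tolist()
        raise ValueError(f"duplicate (peptide_id, sample_id) entries: {pairs}")


def normalize_prm_pair(
    records: pd.DataFrame,
    reference_peptide_ids: list[str],
) -> pd.DataFrame:
    """Normalize modified-peptide intensities within each sample by the
    summed intensity of the five unmodified reference peptides.

    ``normalized = raw(modified peptide, sample) / sum(raw(reference
    peptides, same sample))``.  Every sample must carry all five reference
    peptides with intensity > 0 — a missing or zero reference aborts
    naming the sample and peptide, rather than silently renormalizing over
    a smaller set (which would bias ratios between samples).

    Returns the modified-peptide rows with a ``normalized_intensity``
    column and the per-sample ``reference_sum`` used.
    """
    _check_table(records)
    refs = list(dict.fromkeys(reference_peptide_ids))
    if len(refs) != N_REFERENCE_PEPTIDES:
        raise ValueError(
            f"exactly {N_REFERENCE_PEPTIDES} distinct reference peptides are "
            f"required, got {len(refs)}: {refs}"
        )

    ref_rows = records[records["peptide_id"].isin(refs)]
    if ref_rows["modified"].any():
        bad = ref_rows.loc[ref_rows["modified"], "peptide_id"].unique().tolist()
        raise ValueError(
            f"reference peptides must be unmodified; modified: {bad}"
        )

    sums = {}
    for sample_id, grp in records.groupby("sample_id"):
        present = grp.set_index("peptide_id")["intensity"]
        for ref in refs:
            if ref not in present.index:
                raise ValueError(
                    f"sample {sample_id!r} is missing reference peptide {ref!r}"
                )
            if present[ref] <= 0:
                raise ValueError(
                    f"sample {sample_id!r}: reference peptide {ref!r} has "
                    f"non-positive intensity {present[ref]}"
                )
        sums[sample_id] = float(present[refs].sum())

    out = records[records["modified"]].copy()
    out["reference_sum"] = out["sample_id"].map(sums)
    out["normalized_intensity"] = out["intensity"] / out["reference_sum"]
    return out.reset_index(drop=True)


def log2_pair_ratios(
    normalized: pd.DataFrame,
    numerator_condition: str = "wt",
    denominator_condition: str = "C221A",
    aggregate_to_site: bool = False,
) -> pd.DataFrame:
    """Paired log2 ratios of normalized intensities (numerator condition
    over denominator condition) per peptide per pair.

    Rows whose normalized intensity is zero or whose partner is missing
    are excluded from the ratio table and reported in the ``flag`` column
    of the returned frame instead of raising.  With
    ``aggregate_to_site=True``, ratios of peptides covering the same site
    are averaged after the per-peptide computation.
    """
    needed = {"peptide_id", "site", "pair_id", "condition", "normalized_intensity"}
    missing = needed - set(normalized.columns)
    if missing:
        raise ValueError(f"normalized table is missing columns: {sorted(missing)}")

    rows = []
    for (pair_id, peptide_id), grp in normalized.groupby(["pair_id", "peptide_id"]):
        by_cond = grp.set_index("condition")["normalized_intensity"]
        site = grp["site"].iloc[0]
        rec = {
            "pair_id": pair_id,
            "peptide_id": peptide_id,
            "site": site,
            "flag": "",
            "log2_ratio": np.nan,
        }
        for cond in (numerator_condition, denominator_condition):
            if cond not in by_cond.index:
                rec["flag"] = f"missing-{cond}"
                break
        else:
            num = float(by_cond[numerator_condition])
            den = float(by_cond[denominator_condition])
            rec[f"normalized_{numerator_condition}"] = num
            rec[f"normalized_{denominator_condition}"] = den
            if num <= 0 or den <= 0:
                rec["flag"] = "zero-intensity"
            else:
                rec["log2_ratio"] = float(np.log2(num / den))
        rows.append(rec)
    table = pd.DataFrame(rows)

    if aggregate_to_site:
        ok = table[table["flag"] == ""]
        table = (
            ok.groupby(["pair_id", "site"], as_index=False)
            .agg(log2_ratio=("log2_ratio", "mean"),
                 n_peptides=("peptide_id", "nunique"))
        )
    return table


def normalize_site_by_gel_section(
    site_intensities: pd.DataFrame,
    protein_intensities: pd.DataFrame,
) -> pd.DataFrame:
    """Normalize ubiquitylation-site intensities by the parent protein's
    intensity in the corresponding gel section.

    ``site_intensities`` columns: ``site``, ``section``, ``intensity``;
    ``protein_intensities`` columns: ``section``, ``intensity``.  Sections
    are never mixed; a section with protein intensity 0 (or absent) is an
    error naming the section.
    """
    for col in ("site", "section", "intensity"):
        if col not in site_intensities.columns:
            raise ValueError(f"site table missing column {col!r}")
    for col in ("section", "intensity"):
        if col not in protein_intensities.columns:
            raise ValueError(f"protein table missing column {col!r}")

    prot = protein_intensities.set_index("section")["intensity"]
    if prot.index.duplicated().any():
        raise ValueError(
            f"duplicate sections in protein table: "
            f"{prot.index[prot.index.duplicated()].tolist()}"
        )
    out = site_intensities.copy()
    norms = []
    for _, row in out.iterrows():
        sec = row["section"]
        if sec not in prot.index:
            raise ValueError(f"no protein intensity for gel section {sec!r}")
        p = float(prot[sec])
        if p <= 0:
            raise ValueError(
                f"protein intensity for gel section {sec!r} is {p}; "
                "cannot normalize"
            )
        norms.append(float(row["intensity"]) / p)
    out["normalized_intensity"] = norms
    return out
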