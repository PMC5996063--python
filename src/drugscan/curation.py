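"""Dataset curation: cell-line, drug and assay filters plus instance assembly.

The filters mirror the screening pipeline used to refine a public
pharmacogenomic corpus before model training: cancer types represented by too
few cell lines are dropped; screening-library drugs without a registered
compound identifier or SMILES, or heavier than 1000 g/mol, are removed;
an approved-drug library headed for repurposing is additionally restricted to
organic, single-fragment molecules of 200-650 g/mol.  Identical structures
assayed as separate series remain separate drugs.

Every filter returns ``(retained, report)`` where the report partitions the
input exactly: retained + excluded = input.  All filters are idempotent.
"""

from __future__ import annotations

import math

import pandas as pd
from rdkit import Chem

from .exceptions import ConfigurationError, IntegrityError

DRUG_COLUMNS = [
    "drug_id", "name", "smiles", "molecular_weight",
    "compound_registered", "oncology_flag", "approved_indications",
]


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def filter_cancer_types(cell_lines: pd.DataFrame, min_lines: int = 10):
    """Retain cancer types with at least ``min_lines`` cell lines.

    Returns (retained cell-line table, report).  The report lists each
    excluded type with its cell-line count.
    """
    if min_lines < 1:
        raise ConfigurationError(f"min_lines must be >= 1, got {min_lines}")
    df = pd.DataFrame(cell_lines)
    if len(df) == 0:
        return df, {"retained_types": [], "excluded_types": {}, "n_in": 0, "n_retained": 0, "n_excluded": 0}
    counts = df.groupby("cancer_type", sort=True).size()
    keep = counts.index[counts >= min_lines]
    retained = df[df["cancer_type"].isin(keep)].reset_index(drop=True)
    excluded = {t: int(c) for t, c in counts.items() if c < min_lines}
    report = {
        "retained_types": sorted(keep.tolist()),
        "excluded_types": excluded,
        "n_in": int(len(df)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(df) - len(retained)),
    }
    return retained, report


def filter_gdsc_drugs(registry: pd.DataFrame):
    """Apply the screening-library drug filter.

    Drops drugs without SMILES / compound registration and drugs with
    molecular weight strictly greater than 1000 g/mol.  Entries sharing one
    structure but assayed as distinct series keep their distinct drug_ids and
    are all retained.
    """
    df = pd.DataFrame(registry)
    if len(df) == 0:
        return df, {"n_in": 0, "n_retained": 0, "n_excluded": 0, "excluded": {}}
    no_smiles = df["smiles"].map(_is_missing) if "smiles" in df else pd.Series(True, index=df.index)
    unregistered = (
        ~df["compound_registered"].astype(bool)
        if "compound_registered" in df else pd.Series(False, index=df.index)
    )
    mw = pd.to_numeric(df.get("molecular_weight"), errors="coerce")
    too_heavy = mw > 1000.0  # strictly greater; exactly 1000 g/mol is retained
    drop_registration = no_smiles | unregistered
    drop_weight = too_heavy & ~drop_registration
    retained = df[~(drop_registration | drop_weight)].reset_index(drop=True)
    report = {
        "n_in": int(len(df)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(df) - len(retained)),
        "excluded": {
            "missing_smiles_or_registration": df.loc[drop_registration, "drug_id"].tolist(),
            "molecular_weight_gt_1000": df.loc[drop_weight, "drug_id"].tolist(),
        },
    }
    return retained, report


def _n_fragments(smiles: str) -> int:
    return len([p for p in str(smiles).split(".") if p])


def _is_inorganic(smiles: str) -> bool:
    """No carbon atom anywhere in the molecule; unparseable counts as inorganic."""
    mol = Chem.MolFromSmiles(str(smiles))
    if mol is None:
        return True
    return not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


def filter_approved_drugs(registry: pd.DataFrame):
    """Restrict an approved-drug library to molecules a fingerprint model can encode.

    Four exclusion rules, applied in order; each drug is tallied under the
    first rule it violates:

    1. missing SMILES and/or molecular weight;
    2. molecular weight < 200 g/mol or > 650 g/mol (strict bounds);
    3. two or more disconnected parts ('.' in the SMILES);
    4. inorganic, operationalised as containing no carbon atom.
    """
    df = pd.DataFrame(registry)
    rules = ["missing_smiles_or_mw", "mw_out_of_range", "disconnected_parts", "inorganic"]
    if len(df) == 0:
        return df, {"n_in": 0, "n_retained": 0, "n_excluded": 0,
                    "excluded": {r: [] for r in rules}}
    mw = pd.to_numeric(df.get("molecular_weight"), errors="coerce")
    r1 = df["smiles"].map(_is_missing) | mw.isna()
    r2 = ((mw < 200.0) | (mw > 650.0)) & ~r1
    r3 = df["smiles"].map(lambda s: _n_fragments(s) >= 2) & ~(r1 | r2)
    r4 = df["smiles"].map(_is_inorganic) & ~(r1 | r2 | r3)
    retained = df[~(r1 | r2 | r3 | r4)].reset_index(drop=True)
    report = {
        "n_in": int(len(df)),
        "n_retained": int(len(retained)),
        "n_excluded": int(len(df) - len(retained)),
        "excluded": {
            "missing_smiles_or_mw": df.loc[r1, "drug_id"].tolist(),
            "mw_out_of_range": df.loc[r2, "drug_id"].tolist(),
            "disconnected_parts": df.loc[r3, "drug_id"].tolist(),
            "inorganic": df.loc[r4, "drug_id"].tolist(),
        },
    }
    return retained, report


def assemble_instances(
    cell_lines: pd.DataFrame,
    drugs: pd.DataFrame,
    assays: pd.DataFrame,
    excluded_cell_lines=(),
    excluded_drugs=(),
) -> pd.DataFrame:
    """Join assays against the retained cell lines and drugs.

    One (cell_line_id, drug_id, cancer_type, ln_ic50) instance per assay row
    whose cell line and drug both survived filtering.  Rows referencing known
    excluded entities are dropped silently (that is the point of the filters);
    rows referencing ids never seen at all raise :class:`IntegrityError`, as
    do duplicate (cell line, drug) pairs and non-finite ln_ic50 values.
    """
    cl = pd.DataFrame(cell_lines)
    dr = pd.DataFrame(drugs)
    ay = pd.DataFrame(assays)
    if len(ay) == 0:
        return pd.DataFrame(columns=["cell_line_id", "drug_id", "cancer_type", "ln_ic50"])
    keep_cl = set(cl["cell_line_id"].astype(str))
    keep_dr = set(dr["drug_id"].astype(str))
    known_cl = keep_cl | {str(c) for c in excluded_cell_lines}
    known_dr = keep_dr | {str(d) for d in excluded_drugs}
    a_cl = ay["cell_line_id"].astype(str)
    a_dr = ay["drug_id"].astype(str)
    dangling = ay[~a_cl.isin(known_cl) | ~a_dr.isin(known_dr)]
    if len(dangling) > 0:
        offenders = dangling[["cell_line_id", "drug_id"]].head(5).to_dict("records")
        raise IntegrityError(
            f"{len(dangling)} assay row(s) reference unknown ids, e.g. {offenders}"
        )
    out = ay[a_cl.isin(keep_cl) & a_dr.isin(keep_dr)].copy()
    dup = out.duplicated(subset=["cell_line_id", "drug_id"], keep=False)
    if dup.any():
        pairs = out.loc[dup, ["cell_line_id", "drug_id"]].head(5).to_dict("records")
        raise IntegrityError(f"duplicate (cell line, drug) assay rows, e.g. {pairs}")
    y = pd.to_numeric(out["ln_ic50"], errors="coerce")
    if not y.notna().all() or not pd.Series(y).map(math.isfinite).all():
        raise IntegrityError("non-finite ln_ic50 values in assay table")
    out["ln_ic50"] = y.astype(float)
    ctype = cl.set_index(cl["cell_line_id"].astype(str))["cancer_type"]
    out["cancer_type"] = a_cl.loc[out.index].map(ctype)
    return out[["cell_line_id", "drug_id", "cancer_type", "ln_ic50"]].reset_index(drop=True)
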