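"""In-silico repurposing screen: per-cancer-type sensitivity calls from
predicted ln(IC50) profiles.

Decision rules, all thresholds overridable:

* a cell line is *sensitive* to a drug when its predicted ln(IC50) is
  strictly below -2 (about 0.135 uM);
* a cancer type is *sensitive* to a drug when at least 10% of its cell
  lines are sensitive;
* a drug sensitive in more than 90% of cancer types is flagged pan-cancer
  (nonspecific cytotoxicity) and excluded from repurposing;
* a non-oncology drug is repurposable with >= 1 sensitive type; an oncology
  drug only with a sensitive type outside its approved indications.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import DrugscanError, UsageError
from .evaluation import SENSITIVITY_CUTOFF

logger = logging.getLogger(__name__)

TYPE_THRESHOLD = 0.10   # fraction of a type's cell lines that must respond
PAN_THRESHOLD = 0.90    # sensitive-type fraction above which a drug is pan-cancer


@dataclass(frozen=True)
class RepurposingCall:
    """Sensitivity verdict for one (drug, cancer type) pair."""

    drug_id: str
    cancer_type: str
    n_cell_lines: int
    n_sensitive: int
    fraction_sensitive: float
    type_sensitive: bool

    def to_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class DrugVerdict:
    """Drug-level summary across the panel."""

    drug_id: str
    oncology_flag: bool
    sensitive_types: tuple
    n_types: int
    pan_cancer_flag: bool
    repurposable: bool
    new_indications: tuple

    def to_dict(self):
        d = asdict(self)
        d["sensitive_types"] = ";".join(self.sensitive_types)
        d["new_indications"] = ";".join(self.new_indications)
        return d


def call_sensitivity(predicted_ln_ic50: float, cutoff: float = SENSITIVITY_CUTOFF) -> bool:
    """True iff the prediction is strictly below the cutoff (default -2)."""
    v = float(predicted_ln_ic50)
    if not math.isfinite(v):
        raise UsageError(f"non-finite predicted ln(IC50): {predicted_ln_ic50!r}")
    return v < cutoff


def call_cancer_types(predictions: pd.DataFrame, cutoff: float = SENSITIVITY_CUTOFF,
                      type_threshold: float = TYPE_THRESHOLD) -> list[RepurposingCall]:
    """Per-type calls for one drug.

    ``predictions`` has columns (cancer_type, predicted_ln_ic50) over the
    whole cell-line panel; a type is sensitive when the sensitive fraction
    reaches ``type_threshold`` (>=).
    """
    df = pd.DataFrame(predictions)
    drug_id = str(df["drug_id"].iloc[0]) if "drug_id" in df and len(df) else ""
    calls = []
    for ctype, grp in df.groupby("cancer_type", sort=True):
        n = len(grp)
        if n == 0:  # pragma: no cover - groupby yields non-empty groups
            logger.warning("empty cell-line group for type %s skipped", ctype)
            continue
        n_sens = int(sum(call_sensitivity(v, cutoff) for v in grp["predicted_ln_ic50"]))
        frac = n_sens / n
        calls.append(RepurposingCall(
            drug_id=drug_id, cancer_type=str(ctype), n_cell_lines=n,
            n_sensitive=n_sens, fraction_sensitive=frac,
            type_sensitive=frac >= type_threshold,
        ))
    return calls


def summarize_drug(calls, oncology_flag: bool, approved_indications=(),
                   pan_threshold: float = PAN_THRESHOLD) -> DrugVerdict:
    """Fold per-type calls into a drug verdict.

    Pan-cancer means the sensitive-type fraction strictly exceeds
    ``pan_threshold``; pan-cancer drugs are never repurposable.  Oncology
    drugs additionally need a sensitive type outside their approved
    indications.
    """
    calls = list(calls)
    if not calls:
        raise UsageError("no per-type calls supplied")
    drug_id = calls[0].drug_id
    sensitive = tuple(sorted(c.cancer_type for c in calls if c.type_sensitive))
    n_types = len(calls)
    pan = len(sensitive) / n_types > pan_threshold
    approved = {str(a) for a in approved_indications if str(a)}
    new = tuple(t for t in sensitive if t not in approved) if oncology_flag else sensitive
    repurposable = (not pan) and len(new) >= 1
    return DrugVerdict(drug_id=drug_id, oncology_flag=bool(oncology_flag),
                       sensitive_types=sensitive, n_types=n_types,
                       pan_cancer_flag=pan, repurposable=repurposable,
                       new_indications=new if repurposable else ())


def _parse_indications(value) -> tuple:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    if isinstance(value, str):
        return tuple(v for v in value.split(";") if v)
    return tuple(value)


def scan_library(registry: pd.DataFrame, predict_fn, genomic_fp: pd.DataFrame,
                 panel_types: pd.Series, fingerprinter=None,
                 cutoff: float = SENSITIVITY_CUTOFF,
                 type_threshold: float = TYPE_THRESHOLD,
                 pan_threshold: float = PAN_THRESHOLD):
    """Screen a drug library against the cell-line panel.

    Parameters
    ----------
    registry : drug table (drug_id, smiles, oncology_flag, approved_indications)
    predict_fn : callable X -> predicted ln(IC50); typically
        ``ensemble.predict`` on the concatenated fingerprint matrix
    genomic_fp : binary cell-line x position matrix (index = cell_line_id)
    panel_types : cancer type per cell line, aligned with ``genomic_fp``
    fingerprinter : molecular encoder (default: a fresh MolecularFingerprinter)

    Returns (verdicts DataFrame, calls DataFrame, summary dict).  Drugs whose
    SMILES cannot be encoded are skipped and tallied in the summary.
    """
    from .fingerprints import MolecularFingerprinter, encode_molecular_fingerprint

    if fingerprinter is None:
        fingerprinter = MolecularFingerprinter().fit()
    reg = pd.DataFrame(registry)
    G = genomic_fp.values
    types = np.asarray(panel_types)
    verdicts, all_calls, skipped = [], [], []
    for _, drug in reg.iterrows():
        try:
            fp = encode_molecular_fingerprint(drug["smiles"])
        except DrugscanError:
            logger.warning("drug %s skipped: fingerprint failure", drug["drug_id"])
            skipped.append(str(drug["drug_id"]))
            continue
        X = np.hstack([G, np.tile(fp, (G.shape[0], 1))]).astype(np.uint8)
        preds = pd.DataFrame({
            "drug_id": str(drug["drug_id"]),
            "cancer_type": types,
            "predicted_ln_ic50": predict_fn(X),
        })
        calls = call_cancer_types(preds, cutoff=cutoff, type_threshold=type_threshold)
        verdict = summarize_drug(calls, bool(drug.get("oncology_flag", False)),
                                 _parse_indications(drug.get("approved_indications")),
                                 pan_threshold=pan_threshold)
        all_calls.extend(calls)
        verdicts.append(verdict)
    vdf = pd.DataFrame([v.to_dict() for v in verdicts])
    cdf = pd.DataFrame([c.to_dict() for c in all_calls])
    summary = {
        "n_drugs_screened": int(len(verdicts)),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "n_oncology": int(vdf["oncology_flag"].sum()) if len(vdf) else 0,
        "n_repurposable": int(vdf["repurposable"].sum()) if len(vdf) else 0,
        "n_repurposable_oncology": int((vdf["repurposable"] & vdf["oncology_flag"]).sum()) if len(vdf) else 0,
        "n_repurposable_non_oncology": int((vdf["repurposable"] & ~vdf["oncology_flag"]).sum()) if len(vdf) else 0,
        "n_pan_cancer": int(vdf["pan_cancer_flag"].sum()) if len(vdf) else 0,
    }
    return vdf, cdf, summary
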