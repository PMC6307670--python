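"""Germline-expression triage of TE-containing transcripts.

Candidate transcripts (from a repeat-masking summary) are filtered on masked
length and divergence, then placed into expression tiers against the TPM
distribution of a single-copy reference gene set: "high" means strictly above
the reference 75th percentile, "low" strictly below the 25th.  Percentiles
use linear interpolation between closest ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TETranscriptRecord",
    "ExpressionTiers",
    "filter_te_transcripts",
    "expression_tiers",
    "classify_expression",
    "superfamily_summary",
    "te_fraction_bands",
]


@dataclass(frozen=True)
class TETranscriptRecord:
    transcript_id: str
    masked_bp: int
    divergence: float
    te_name: str
    te_class: str  # "DNA" | "RNA"
    superfamily: str
    transcript_length: int
    tpm: float

    def __post_init__(self):
        if self.masked_bp < 0:
            raise ValueError(f"negative masked_bp for {self.transcript_id}")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError(f"divergence outside [0,1] for {self.transcript_id}")
        if self.masked_bp > self.transcript_length:
            raise ValueError(
                f"masked_bp exceeds transcript length for {self.transcript_id}")
        if self.tpm < 0:
            raise ValueError(f"negative TPM for {self.transcript_id}")


@dataclass(frozen=True)
class ExpressionTiers:
    q1: float
    q3: float
    n_reference: int

    def __post_init__(self):
        if self.q1 > self.q3:
            raise ValueError("q1 > q3")


def filter_te_transcripts(records, min_masked_bp: int = 200,
                          max_divergence: float = 0.20):
    """Retain records with masked_bp >= min_masked_bp and
    divergence <= max_divergence (both thresholds inclusive); order
    preserved."""
    return [r for r in records
            if r.masked_bp >= min_masked_bp and r.divergence <= max_divergence]


def expression_tiers(reference_tpms) -> ExpressionTiers:
    """25th/75th percentiles of the reference TPM distribution
    (linear interpolation between closest ranks)."""
    tpms = np.asarray(reference_tpms, dtype=float)
    if tpms.size < 4:
        raise ValueError("need at least 4 reference TPM values")
    q1, q3 = np.percentile(tpms, [25.0, 75.0])
    return ExpressionTiers(q1=float(q1), q3=float(q3), n_reference=tpms.size)


def classify_expression(tpm: float, tiers: ExpressionTiers) -> str:
    """Tier of one TPM value: 'high' iff tpm > q3 (strict), 'low' iff
    tpm < q1 (strict), else 'mid'."""
    if tpm < 0:
        raise ValueError("negative TPM")
    if tpm > tiers.q3:
        return "high"
    if tpm < tiers.q1:
        return "low"
    return "mid"


def superfamily_summary(records) -> pd.DataFrame:
    """Grouped transcript counts per (te_class, superfamily)."""
    rows = [(r.te_class, r.superfamily) for r in records]
    df = pd.DataFrame(rows, columns=["te_class", "superfamily"])
    out = (df.value_counts().rename("n_transcripts").reset_index()
           .sort_values(["te_class", "n_transcripts"],
                        ascending=[True, False], ignore_index=True))
    return out


def te_fraction_bands(records) -> pd.DataFrame:
    """Fraction of each transcript covered by TE sequence, binned into the
    chimera-diagnosis bands <60%, 60-90%, >=90%."""
    rows = []
    for r in records:
        frac = r.masked_bp / r.transcript_length
        if frac >= 0.90:
            band = ">=90%"
        elif frac >= 0.60:
            band = "60-90%"
        else:
            band = "<60%"
        rows.append((r.transcript_id, frac, band))
    return pd.DataFrame(rows, columns=["transcript_id", "te_fraction", "band"])
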