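"""mtDNA copy number from paired qPCR Ct values.

With ideal doubling per cycle, the template amount is proportional to
2^(-Ct), so the mitochondrial-to-nuclear template ratio — the mtDNA copy
number per nuclear genome equivalent — is

    CN = 2 ** (Ct_nuclear - Ct_mito)

using a mitochondrial amplicon (ND1) and a single-copy nuclear amplicon
(PPIA). No amplification-efficiency correction is applied. Variant burdens
are normalized by division (variants per copy-number equivalent); a
per-1000-copies scaling is available for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import MissingDataError, ParameterError

PLAUSIBLE_CT_RANGE = (0.0, 45.0)


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    ct_nd1: float | None
    ct_ppia: float | None

    def __post_init__(self):
        for label, ct in (("ND1", self.ct_nd1), ("PPIA", self.ct_ppia)):
            if ct is not None and not PLAUSIBLE_CT_RANGE[0] < ct < PLAUSIBLE_CT_RANGE[1]:
                warnings.warn(
                    f"{self.sample_id}: {label} Ct {ct} outside plausible qPCR range "
                    f"{PLAUSIBLE_CT_RANGE}",
                    stacklevel=3,
                )


def mtdna_cn(record: CtRecord) -> float:
    """Copies per nuclear genome equivalent: 2^(PPIA Ct - ND1 Ct)."""
    if record.ct_nd1 is None or record.ct_ppia is None:
        raise MissingDataError(f"{record.sample_id}: missing Ct value")
    return float(2.0 ** (record.ct_ppia - record.ct_nd1))


def normalize_burden(count: int, cn: float, per: float = 1.0) -> float:
    """Variant count per `per` copy-number equivalents (default: per copy)."""
    if cn <= 0:
        raise ParameterError(f"copy number must be positive, got {cn}")
    if count < 0:
        raise ParameterError("count must be nonnegative")
    return count / cn * per


def read_ct_csv(path) -> list[CtRecord]:
    """CSV with columns sample, ct_nd1, ct_ppia."""
    df = pd.read_csv(path)
    return [
        CtRecord(
            sample_id=str(r.sample),
            ct_nd1=None if pd.isna(r.ct_nd1) else float(r.ct_nd1),
            ct_ppia=None if pd.isna(r.ct_ppia) else float(r.ct_ppia),
        )
        for r in df.itertuples(index=False)
    ]


def cn_table(records: list[CtRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.sample_id,
                "ct_nd1": r.ct_nd1,
                "ct_ppia": r.ct_ppia,
                "mtdna_cn": mtdna_cn(r) if (r.ct_nd1 is not None and r.ct_ppia is not None) else float("nan"),
            }
        )
    return pd.DataFrame(rows)
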