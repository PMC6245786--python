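"""Hard genotype-level filters applied to the two-sample table before mapping.

Records are removed whole (never set to missing per sample) when either
pool's genotype quality falls below the threshold, when the site is
multi-allelic, when a call is missing, or -- if the input VCF carries an
upstream FILTER annotation -- when FILTER is not PASS.  Each removed record
is attributed to exactly one rule, the first that fires in the order
``non_pass``, ``multi_allelic``, ``missing``, ``low_gq``, so the removal
tally partitions the removed set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .variants import VariantRecord, check_sorted

RULE_ORDER = ("non_pass", "multi_allelic", "missing", "low_gq")


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for the hard filters.

    ``min_gq`` removes records where *either* sample's GQ is strictly below
    the threshold (GQ exactly at the threshold is retained).
    """

    min_gq: int = 5
    biallelic_only: bool = True
    drop_missing: bool = True
    require_pass: bool = True

    def __post_init__(self) -> None:
        if self.min_gq < 0:
            raise ValueError("min_gq must be >= 0")


def failing_rule(rec: VariantRecord, cfg: QcConfig) -> str | None:
    """Name of the first filter rule the record fails, or None if it passes."""
    if cfg.require_pass and rec.filter not in ("PASS", "."):
        return "non_pass"
    if cfg.biallelic_only and len(rec.alts) > 1:
        return "multi_allelic"
    if cfg.drop_missing and any(c.is_missing for c in rec.calls.values()):
        return "missing"
    if any(c.gq < cfg.min_gq for c in rec.calls.values()):
        return "low_gq"
    return None


def apply_hard_filters(
    records: Sequence[VariantRecord], cfg: QcConfig | None = None
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Filter the table; returns (retained records, per-rule removal counts).

    Input must be sorted by (chromosome, position); the offending position
    is reported otherwise.  The counts always contain every rule name and
    sum to ``len(records) - len(retained)``.
    """
    cfg = cfg or QcConfig()
    check_sorted(records)
    counts = {rule: 0 for rule in RULE_ORDER}
    kept: list[VariantRecord] = []
    for rec in records:
        rule = failing_rule(rec, cfg)
        if rule is None:
            kept.append(rec)
        else:
            counts[rule] += 1
    return kept, counts
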