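"""Shared result records for heterochrony detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["HeterochronyRecord", "HeterochronyReport"]


@dataclass(frozen=True)
class HeterochronyRecord:
    """One flagged shift: ``where`` is a taxon (continuous criterion) or an
    internal node (event-pair cracking); ``direction`` is 'earlier' or
    'later'; ``statistic`` is the taxon value or the event's TRC; the CI
    bounds are the interval the statistic fell outside of."""

    where: str
    event: str
    direction: str
    statistic: float
    ci_lower: float
    ci_upper: float
    method: str = ""


@dataclass
class HeterochronyReport:
    records: list[HeterochronyRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        cols = ["where", "event", "direction", "statistic", "ci_lower", "ci_upper", "method"]
        return pd.DataFrame(
            [[getattr(r, c) for c in cols] for r in self.records], columns=cols
        )
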