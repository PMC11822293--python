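"""Sensor layout: channel -> (region, hemisphere) assignment.

The default layout mirrors a 275-channel axial-gradiometer MEG system grouped
into 11 sensor regions: five left/right lobar pairs (central, frontal,
occipital, parietal, temporal) plus the midline cerebral-fissure group, with
three ungrouped reference channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: region code -> (hemisphere, number of channels in the default layout)
REGION_DEF: dict[str, tuple[str, int]] = {
    "CL": ("left", 24),
    "FL": ("left", 31),
    "OL": ("left", 19),
    "PL": ("left", 22),
    "TL": ("left", 33),
    "CR": ("right", 24),
    "FRt": ("right", 33),
    "OR": ("right", 19),
    "PR": ("right", 22),
    "TR": ("right", 34),
    "CF": ("midline", 11),
}

REGIONS: tuple[str, ...] = tuple(REGION_DEF)

#: lobar pairs usable for hemispheric asymmetry (midline CF excluded)
REGION_PAIRS: dict[str, tuple[str, str]] = {
    "C": ("CL", "CR"),
    "F": ("FL", "FRt"),
    "O": ("OL", "OR"),
    "P": ("PL", "PR"),
    "T": ("TL", "TR"),
}


@dataclass
class SensorRegionMap:
    """Channel-to-region assignment backed by a DataFrame.

    Columns: ``channel_label``, ``region``, ``hemisphere``.  Reference or
    otherwise ungrouped channels carry region ``""`` and hemisphere ``""``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"channel_label", "region", "hemisphere"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"layout table needs columns {sorted(required)}")
        if self.table["channel_label"].duplicated().any():
            dupes = self.table.loc[
                self.table["channel_label"].duplicated(), "channel_label"
            ].tolist()
            raise ValueError(f"duplicate channel labels: {dupes}")
        bad = set(self.table["region"]) - set(REGIONS) - {""}
        if bad:
            raise ValueError(f"unknown regions: {sorted(bad)}")

    @property
    def channel_labels(self) -> list[str]:
        return self.table["channel_label"].tolist()

    @property
    def grouped(self) -> pd.DataFrame:
        """Rows for channels that belong to one of the 11 regions."""
        return self.table[self.table["region"] != ""]

    def channels_in_region(self, region: str) -> list[str]:
        if region not in REGIONS:
            raise KeyError(f"unknown region {region!r}")
        sel = self.table["region"] == region
        return self.table.loc[sel, "channel_label"].tolist()

    def region_of(self, channel_label: str) -> str:
        sel = self.table["channel_label"] == channel_label
        if not sel.any():
            raise KeyError(f"unknown channel {channel_label!r}")
        return self.table.loc[sel, "region"].iloc[0]

    def hemisphere_of(self, channel_label: str) -> str:
        sel = self.table["channel_label"] == channel_label
        if not sel.any():
            raise KeyError(f"unknown channel {channel_label!r}")
        return self.table.loc[sel, "hemisphere"].iloc[0]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorRegionMap":
        table = pd.read_csv(path, keep_default_na=False)
        return cls(table=table)


def default_layout() -> SensorRegionMap:
    """Build the default 275-channel layout.

    272 channels are grouped into the 11 regions (CL 24, FL 31, OL 19, PL 22,
    TL 33, CR 24, FRt 33, OR 19, PR 22, TR 34, CF 11); three reference
    channels (REF1-REF3) are ungrouped.  Deterministic.
    """
    rows = []
    for region, (hemi, n) in REGION_DEF.items():
        for i in range(1, n + 1):
            rows.append(
                {
                    "channel_label": f"{region}{i:02d}",
                    "region": region,
                    "hemisphere": hemi,
                }
            )
    for i in range(1, 4):
        rows.append({"channel_label": f"REF{i}", "region": "", "hemisphere": ""})
    return SensorRegionMap(table=pd.DataFrame(rows))
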