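"""Study design: regions, groups, sexes and per-region sample layout."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


class ParameterError(ValueError):
    """Raised for invalid generator parameters."""


@dataclass
class StudyDesign:
    """The 16-channel-per-region two-group design.

    Defaults match the emulated study: four regions, 8 PME vs 8 PSE animals
    per region with a 4M:4F sex split in each group. Litter identity is
    carried as metadata only; sex is recorded per sample but the contrast is
    treatment alone.
    """

    regions: tuple[str, ...] = ("M1", "S1", "DLS", "DMS")
    n_per_group: int = 8
    sex_split: tuple[int, int] = (4, 4)  # (males, females) per group
    groups: tuple[str, str] = ("PME", "PSE")
    litter_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if set(self.groups) != {"PME", "PSE"}:
            raise ParameterError("groups must be exactly {PME, PSE}")
        if sum(self.sex_split) != self.n_per_group:
            raise ParameterError("sex counts must sum to n_per_group per group")
        if self.n_per_group < 1 or not self.regions:
            raise ParameterError("need >= 1 sample per group and >= 1 region")
        n_total = self.n_samples
        if self.litter_ids is not None and len(self.litter_ids) != n_total:
            raise ParameterError(f"litter_ids must have length {n_total}")

    @property
    def n_samples(self) -> int:
        """Total samples per region (= 2 x n_per_group)."""
        return 2 * self.n_per_group

    def sample_table(self, region: str) -> pd.DataFrame:
        """Per-sample metadata for one region, indexed by sample name.

        Sample names follow ``<group>_<sex>_<replicate>``.
        """
        rows = {}
        i_lit = 0
        for group in ("PME", "PSE"):
            rep = 0
            for sex, count in zip(("M", "F"), self.sex_split):
                for _ in range(count):
                    rep += 1
                    name = f"{group}_{sex}_{rep}"
                    litter = self.litter_ids[i_lit] if self.litter_ids else ""
                    rows[name] = {"group": group, "sex": sex, "region": region,
                                  "litter": litter}
                    i_lit += 1
        return pd.DataFrame.from_dict(rows, orient="index")
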