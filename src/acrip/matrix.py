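"""Features x samples quantification matrix with group/replicate metadata.

Sample ids follow the ``GROUP_REPLICATE`` convention (e.g. ``WT_1``,
``FAD_2``); the group label is everything before the last underscore.
Missing values (NaN) encode "not detected" and are permitted only for
intensity-like kinds — zero is a measurement, NaN is absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

KINDS = ("count", "tpm", "fot", "intensity")
_MISSING_OK = ("intensity", "fot")


def split_sample_id(sample: str) -> tuple[str, int]:
    """Parse ``WT_2`` -> ``("WT", 2)``."""
    group, _, rep = sample.rpartition("_")
    if not group or not rep.isdigit():
        raise FormatError(f"sample id {sample!r} does not follow GROUP_REPLICATE")
    return group, int(rep)


@dataclass
class OmicsMatrix:
    values: pd.DataFrame  # features (rows) x samples (columns)
    kind: str = "count"
    assay: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any() and self.kind not in _MISSING_OK:
            raise FormatError(f"missing values not allowed for kind={self.kind}")
        with np.errstate(invalid="ignore"):
            if (vals < 0).any():
                i, j = np.argwhere(vals < 0)[0]
                raise FormatError(
                    f"negative value at feature {self.values.index[i]!r}, "
                    f"sample {self.values.columns[j]!r}"
                )
        for s in self.values.columns:
            split_sample_id(s)

    # -- metadata ---------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def group_of(self, sample: str) -> str:
        return split_sample_id(sample)[0]

    def replicate_of(self, sample: str) -> int:
        return split_sample_id(sample)[1]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            g = self.group_of(s)
            if g not in seen:
                seen.append(g)
        return seen

    def samples_of_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.group_of(s) == group]

    # -- numerics ---------------------------------------------------------
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0, skipna=True)

    def cpm(self) -> pd.DataFrame:
        """Depth-normalized values: counts per million of the column total."""
        lib = self.library_sizes()
        if (lib <= 0).any():
            bad = lib.index[lib <= 0][0]
            raise ConfigError(f"sample {bad!r} has zero library size")
        return self.values.div(lib, axis=1) * 1e6

    def subset_samples(self, samples: list[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(samples)].copy(), kind=self.kind, assay=self.assay)

    def sorted(self) -> "OmicsMatrix":
        v = self.values.sort_index(axis=0).sort_index(axis=1)
        return OmicsMatrix(v, kind=self.kind, assay=self.assay)
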