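"""Packaged example datasets.

Three small published datasets ship with the package:

* ``covid_china`` -- 66 daily COVID-19 death counts recorded in China,
  23 January to 28 March 2020 (uncensored counts).
* ``leukemia_remission`` -- remission times in weeks for 30 leukemia
  patients under a common treatment; 5 times are right-censored.
* ``pelvic_tumor`` -- 21 pelvic-tumor recurrence times in months after
  hemipelvis endoprosthesis reconstruction; heavily censored, with a
  plausible cured sub-population.

In the source publications censored values are flagged with "+"
(leukemia) or "*" (pelvic tumor); both map to ``event = 0`` here.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .inference import CensoredSample
from .io import read_censored, read_counts

__all__ = ["PackagedDataset", "load_dataset", "DATASET_NAMES"]

DATASET_NAMES = ("covid_china", "leukemia_remission", "pelvic_tumor")

_NOTES = {
    "covid_china": "66 daily COVID-19 death counts, China, 23 Jan - 28 Mar 2020",
    "leukemia_remission": "30 leukemia remission times (weeks); '+'-flagged times censored",
    "pelvic_tumor": "21 pelvic-tumor recurrence times (months); '*'-flagged times censored",
}


@dataclass(frozen=True)
class PackagedDataset:
    name: str
    sample: np.ndarray | CensoredSample
    n: int
    source_note: str

    @property
    def is_censored(self) -> bool:
        return isinstance(self.sample, CensoredSample)


def load_dataset(name: str) -> PackagedDataset:
    """Load one of the packaged datasets by name."""
    if name not in DATASET_NAMES:
        raise ValueError(f"unknown dataset {name!r}; available: {', '.join(DATASET_NAMES)}")
    ref = resources.files("pebwe.data") / f"{name}.csv"
    with resources.as_file(ref) as path:
        sample = read_counts(path) if name == "covid_china" else read_censored(path)
    return PackagedDataset(name=name, sample=sample, n=len(sample), source_note=_NOTES[name])
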