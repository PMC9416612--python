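"""Container for 1D NMR spectral datasets.

A :class:`SpectraDataset` bundles the ppm axis, the sample-by-variable
intensity matrix and the per-sample metadata table (subject, replicate,
class) that every pipeline stage transforms.  The axis is stored in
ascending ppm order internally; display/report code reverses it to follow
the NMR convention of descending chemical shift.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("sample_id", "subject_id", "replicate_index", "class_label")


@dataclasses.dataclass
class SpectraDataset:
    """ppm axis + intensity matrix + sample metadata.

    Parameters
    ----------
    ppm : (P,) ndarray
        Chemical-shift axis, strictly monotone increasing.
    intensities : (n, P) ndarray
        One spectrum per row, aligned to ``ppm``.
    samples : DataFrame
        One row per spectrum with columns ``sample_id``, ``subject_id``,
        ``replicate_index`` and ``class_label``.
    processing_log : list of dict
        Append-only record of the steps applied so far.
    truth : dict or None
        Simulation ground truth (dilution factors, planted shifts, marker
        variables) when the dataset is synthetic.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    samples: pd.DataFrame
    processing_log: list[dict[str, Any]] = dataclasses.field(default_factory=list)
    truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise ValueError("ppm axis must be one-dimensional")
        if not np.all(np.diff(self.ppm) > 0):
            raise ValueError("ppm axis must be strictly increasing")
        if self.intensities.shape[1] != self.ppm.size:
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} columns "
                f"but the ppm axis has {self.ppm.size} points"
            )
        if len(self.samples) != self.intensities.shape[0]:
            raise ValueError("sample table length does not match intensity rows")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample table lacks columns: {missing}")
        per_subject = self.samples.groupby("subject_id")["class_label"].nunique()
        if (per_subject > 1).any():
            bad = per_subject[per_subject > 1].index.tolist()
            raise ValueError(f"subjects with inconsistent class labels: {bad}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_variables(self) -> int:
        return self.ppm.size

    @property
    def class_labels(self) -> np.ndarray:
        return self.samples["class_label"].to_numpy()

    def log_step(self, name: str, **params: Any) -> None:
        """Append one record to the processing log."""
        self.processing_log.append({"step": name, **params})

    def copy_with(
        self,
        ppm: np.ndarray | None = None,
        intensities: np.ndarray | None = None,
    ) -> "SpectraDataset":
        """Shallow-copy the dataset, optionally replacing axis/matrix.

        The sample table is never reordered by pipeline stages, so it is
        shared; the processing log is copied so the new object owns its
        history.
        """
        return SpectraDataset(
            ppm=self.ppm if ppm is None else ppm,
            intensities=self.intensities if intensities is None else intensities,
            samples=self.samples,
            processing_log=list(self.processing_log),
            truth=self.truth,
        )

    def subset_samples(self, mask: np.ndarray) -> "SpectraDataset":
        """Row-subset (e.g. after outlier removal), preserving order."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        out = SpectraDataset(
            ppm=self.ppm,
            intensities=self.intensities[idx],
            samples=self.samples.iloc[idx].reset_index(drop=True),
            processing_log=list(self.processing_log),
            truth=self.truth,
        )
        return out

    # ------------------------------------------------------------------
    # Native on-disk format: one delimited matrix file (first row = ppm
    # axis, then one row per sample) plus one metadata table.
    def write(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        matrix_path = Path(matrix_path)
        header = "\t".join(format(v, ".6f") for v in self.ppm)
        with open(matrix_path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.intensities, fmt="%.8g", delimiter="\t")
        self.samples.loc[:, list(SAMPLE_COLUMNS)].to_csv(
            metadata_path, sep="\t", index=False
        )

    @classmethod
    def read(cls, matrix_path: str | Path, metadata_path: str | Path) -> "SpectraDataset":
        raw = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        ppm, intensities = raw[0], raw[1:]
        samples = pd.read_csv(metadata_path, sep="\t")
        return cls(ppm=ppm, intensities=intensities, samples=samples)


def make_sample_table(
    subject_ids: list,
    class_labels: list,
    replicates: int,
) -> pd.DataFrame:
    """Expand subject-level labels into a per-spectrum sample table."""
    rows = []
    for subj, cls in zip(subject_ids, class_labels):
        for r in range(1, replicates + 1):
            rows.append(
                {
                    "sample_id": f"{subj}_r{r}",
                    "subject_id": subj,
                    "replicate_index": r,
                    "class_label": cls,
                }
            )
    return pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
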