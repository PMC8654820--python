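"""Chunked on-disk descriptor archives (HDF5 + JSON manifest).

Records are grouped by amino-acid type; channels are stored as float32 with
lzf chunk compression and round-trip bit-identically. The manifest carries
counts, a label histogram and full generator provenance (seeds, parameters)
and is hashed so trained models can pin the exact dataset they saw.
"""
from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .descriptors import DescriptorRecord

__all__ = ["DatasetArchive"]

_META_COLS = ["structure_id", "resolution_tag", "chain", "resnum", "flag"]


class DatasetArchive:
    """Append-while-building, read-back-by-amino-acid descriptor store."""

    def __init__(self, path, mode: str = "r"):
        self.path = str(path)
        self._h5 = h5py.File(self.path, mode)
        if mode in ("w", "w-", "x"):
            self._h5.create_group("records")
            self._h5.attrs["manifest"] = json.dumps({"counts": {}, "provenance": {}})

    # -- writing --------------------------------------------------------

    @classmethod
    def create(cls, path, provenance: Optional[dict] = None) -> "DatasetArchive":
        arc = cls(path, mode="w")
        if provenance:
            arc._set_manifest({"counts": {}, "provenance": provenance})
        return arc

    def add_records(self, records: Sequence[DescriptorRecord]) -> None:
        by_aa: dict = {}
        for r in records:
            by_aa.setdefault(r.amino_acid, []).append(r)
        for aa, recs in by_aa.items():
            grp = self._group(aa, template=recs[0])
            n0 = grp["labels"].shape[0]
            n1 = n0 + len(recs)
            for name in ("channels", "labels", "centers", *_META_COLS):
                grp[name].resize(n1, axis=0)
            grp["channels"][n0:n1] = np.stack([r.channels for r in recs])
            grp["labels"][n0:n1] = [np.nan if r.label is None else r.label for r in recs]
            grp["centers"][n0:n1] = np.stack([r.center for r in recs])
            for col in _META_COLS:
                vals = [getattr(r, col) for r in recs]
                grp[col][n0:n1] = [str(v) for v in vals] if col != "resnum" else vals
        man = self.manifest
        for aa, recs in by_aa.items():
            man["counts"][aa] = man["counts"].get(aa, 0) + len(recs)
        self._set_manifest(man)

    def _group(self, aa: str, template: DescriptorRecord) -> h5py.Group:
        root = self._h5["records"]
        if aa in root:
            return root[aa]
        grp = root.create_group(aa)
        shape = template.channels.shape
        str_t = h5py.string_dtype()
        grp.create_dataset("channels", shape=(0, *shape), maxshape=(None, *shape),
                           dtype="f4", chunks=(1, *shape), compression="lzf")
        grp.create_dataset("labels", shape=(0,), maxshape=(None,), dtype="f8")
        grp.create_dataset("centers", shape=(0, 3), maxshape=(None, 3), dtype="f8")
        for col in _META_COLS:
            dt = "i8" if col == "resnum" else str_t
            grp.create_dataset(col, shape=(0,), maxshape=(None,), dtype=dt)
        grp.attrs["edge"] = template.edge
        grp.attrs["spacing"] = template.spacing
        return grp

    def finalize(self, extra_provenance: Optional[dict] = None) -> None:
        """Recompute the label histogram and close the file for writing."""
        man = self.manifest
        labels = []
        for aa in self.amino_acids:
            lab = self._h5[f"records/{aa}/labels"][:]
            labels.extend(lab[np.isfinite(lab)].tolist())
        hist, edges = np.histogram(labels, bins=10, range=(0.0, 1.0))
        man["label_histogram"] = {"bin_edges": edges.tolist(), "counts": hist.tolist()}
        if extra_provenance:
            man["provenance"].update(extra_provenance)
        self._set_manifest(man)
        self._h5.close()
        self._h5 = h5py.File(self.path, "r")

    # -- reading --------------------------------------------------------

    @property
    def manifest(self) -> dict:
        return json.loads(self._h5.attrs["manifest"])

    def _set_manifest(self, man: dict) -> None:
        self._h5.attrs["manifest"] = json.dumps(man, sort_keys=True)

    @property
    def amino_acids(self) -> list:
        return sorted(self._h5["records"].keys())

    def count(self, amino_acid: str) -> int:
        if amino_acid not in self._h5["records"]:
            return 0
        return self._h5[f"records/{amino_acid}/labels"].shape[0]

    def load(self, amino_acid: str, indices=None):
        """(channels float32 (n,5,N,N,N), labels (n,), metadata DataFrame)."""
        grp = self._h5[f"records/{amino_acid}"]
        if indices is None:
            sel = slice(None)
        else:
            sel = np.asarray(sorted(indices))
        channels = grp["channels"][sel]
        labels = grp["labels"][sel]
        meta = pd.DataFrame({col: [v.decode() if isinstance(v, bytes) else v
                                   for v in grp[col][sel]]
                             for col in _META_COLS})
        return channels, labels, meta

    def load_records(self, amino_acid: str, indices=None) -> list:
        """Rehydrate stored rows as :class:`DescriptorRecord` objects."""
        grp = self._h5[f"records/{amino_acid}"]
        channels, labels, meta = self.load(amino_acid, indices)
        centers = grp["centers"][slice(None) if indices is None else np.asarray(sorted(indices))]
        out = []
        for i in range(len(labels)):
            out.append(DescriptorRecord(
                channels=channels[i], amino_acid=amino_acid,
                structure_id=meta.structure_id[i], resolution_tag=meta.resolution_tag[i],
                chain=meta.chain[i], resnum=int(meta.resnum[i]), center=centers[i],
                edge=float(grp.attrs["edge"]), spacing=float(grp.attrs["spacing"]),
                label=None if np.isnan(labels[i]) else float(labels[i]),
                flag=str(meta.flag[i])))
        return out

    def manifest_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.manifest, sort_keys=True).encode()).hexdigest()

    def close(self) -> None:
        self._h5.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()
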