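"""Five-channel voxel descriptors and labeled-dataset assembly.

Channel 0 is the observed map boxed at the residue centroid; channels 1-4
are the calculated density of the model's C, N, O and S atoms respectively,
each synthesized at B_iso = 2.0 from the hydrogen-stripped, B-reset
structure and boxed on the same lattice. The label is the bCC of the model
against the correct (high-resolution) observed map.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .boxes import extract_box, residue_centroid, rotate_voxels
from .density import suggest_grid, synthesize_map
from .errors import DegenerateBoxError
from .maps import DensityMap
from .metrics import CALC_B_ISO, CALC_SPACING, bcc
from .scattering import ScatteringTable, default_table
from .structure import Residue, Structure, set_uniform_bfactor, split_by_element, strip

__all__ = ["CHANNEL_ELEMENTS", "DescriptorRecord", "DescriptorBuilder",
           "build_descriptors", "label_record", "balance_dataset",
           "augment_rotations"]

# channel identities: observed map + per-element calculated density
CHANNEL_ELEMENTS = ("C", "N", "O", "S")


@dataclass
class DescriptorRecord:
    """One residue's 5-channel voxel tensor plus metadata and (optional) label."""

    channels: np.ndarray            # (5, N, N, N) float32
    amino_acid: str
    structure_id: str
    resolution_tag: str
    chain: str
    resnum: int
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    edge: float = 12.0
    spacing: float = 0.5
    label: Optional[float] = None   # bCC_act in [-1, 1]
    flag: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 5:
            raise ValueError("channels must be (5, N, N, N)")
        n = self.channels.shape[1]
        if self.channels.shape[1:] != (n, n, n):
            raise ValueError("channel grids must be cubic and equal")
        if self.label is not None and not np.isfinite(self.label):
            raise ValueError("label must be finite")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    @property
    def residue_id(self) -> str:
        return f"{self.chain}{self.resnum}"

    def calc_sum(self) -> np.ndarray:
        """Combined calculated-density box = sum of the element channels."""
        return self.channels[1:].sum(axis=0)


class DescriptorBuilder:
    """Precomputes per-element calculated maps for one model structure.

    Splitting and synthesis are done once per structure; each residue then
    needs only five box extractions. Use this (rather than repeated
    :func:`build_descriptors` calls) when boxing many residues.
    """

    def __init__(self, structure: Structure, obs_map: DensityMap,
                 table: ScatteringTable = None, edge: float = 12.0,
                 spacing: float = 0.5, calc_spacing: float = CALC_SPACING,
                 resolution_tag: str = ""):
        self.structure = structure
        self.obs_map = obs_map
        self.table = table or default_table()
        self.edge = float(edge)
        self.spacing = float(spacing)
        self.resolution_tag = resolution_tag
        prep = set_uniform_bfactor(
            strip(structure, drop_waters=False, drop_hetero=False, drop_hydrogens=True),
            CALC_B_ISO)
        dims = suggest_grid(structure.cell, calc_spacing)
        by_el = split_by_element(prep, CHANNEL_ELEMENTS)
        self.element_maps = {
            el: synthesize_map(by_el[el], dims, b_override=CALC_B_ISO, table=self.table)
            for el in CHANNEL_ELEMENTS
        }

    def build(self, residue: Residue) -> DescriptorRecord:
        center = residue_centroid(residue)
        boxes = [extract_box(self.obs_map, center, self.edge, self.spacing)]
        boxes += [extract_box(self.element_maps[el], center, self.edge, self.spacing)
                  for el in CHANNEL_ELEMENTS]
        channels = np.stack([b.values for b in boxes]).astype(np.float32)
        flag = ""
        if float(np.var(channels[0])) == 0.0:
            flag = "degenerate-obs"
        return DescriptorRecord(
            channels=channels, amino_acid=residue.name,
            structure_id=self.structure.id, resolution_tag=self.resolution_tag,
            chain=residue.chain, resnum=residue.seqnum, center=center,
            edge=self.edge, spacing=self.spacing, flag=flag)


def build_descriptors(structure: Structure, obs_map: DensityMap, residue: Residue,
                      table: ScatteringTable = None, edge: float = 12.0,
                      spacing: float = 0.5) -> DescriptorRecord:
    """Five-channel descriptor for one residue (unlabeled).

    Convenience wrapper that builds the per-element maps for a single call;
    use :class:`DescriptorBuilder` for many residues of one structure.
    """
    if structure.get_residue(residue.chain, residue.seqnum) is None:
        raise ValueError(f"residue {residue.key} not in structure")
    return DescriptorBuilder(structure, obs_map, table, edge, spacing).build(residue)


def label_record(record: DescriptorRecord, correct_obs_map: DensityMap) -> DescriptorRecord:
    """Attach bCC_act: correlation of the correct map's box with the model's
    combined calculated box. Degenerate boxes leave the record unlabeled
    with a flag instead of raising."""
    correct_box = extract_box(correct_obs_map, record.center, record.edge, record.spacing)
    try:
        label = bcc(correct_box.values, record.calc_sum().astype(float))
    except DegenerateBoxError:
        return replace(record, label=None, flag="unlabeled-degenerate")
    return replace(record, label=float(label))


def balance_dataset(records: Sequence[DescriptorRecord], n_bins: int = 10,
                    per_bin_cap: int = 200, seed: int = 0) -> list:
    """Flatten the label histogram by capped per-bin downsampling.

    Labels are histogrammed into ``n_bins`` equal bins over [0, 1] (values
    outside are clipped into the edge bins); each bin is downsampled
    uniformly at random to at most ``per_bin_cap`` records, and the output
    order is shuffled — all seeded. Unlabeled records are dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    rng = np.random.default_rng(seed)
    labeled = [r for r in records if r.label is not None]
    if not labeled:
        return []
    labels = np.clip([r.label for r in labeled], 0.0, 1.0 - 1e-12)
    bins = np.floor(labels * n_bins).astype(int)
    keep: list = []
    for b in range(n_bins):
        idx = np.flatnonzero(bins == b)
        if len(idx) > per_bin_cap:
            idx = rng.choice(idx, size=per_bin_cap, replace=False)
        keep.extend(idx.tolist())
    keep = np.array(sorted(keep))
    rng.shuffle(keep)
    return [labeled[i] for i in keep]


def augment_rotations(record: DescriptorRecord) -> list:
    """The 24 cube-rotated copies of a record (rotation 0 is the input).

    All five channels rotate jointly; the label is orientation-free and
    carries over unchanged.
    """
    out = []
    for k in range(24):
        out.append(replace(record, channels=rotate_voxels(record.channels, k),
                           flag=record.flag))
    return out
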