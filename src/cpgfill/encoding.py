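"""Model-input encoding.

A prediction target (one CpG site) is encoded as

* a one-hot DNA window (default 1001 bp) centred on the site's C, with
  ``N`` bases and off-chromosome overhang encoded as all-zero rows, and
* one neighbor vector per profile: the methylation levels of the nearest
  ``k`` covered CpG sites on each side (default 25) concatenated with their
  normalised base-pair distances, giving a length-100 vector.

Neighbor slots beyond the profile's data are padded with level 0.5 and
distance 1.0 (maximally uninformative values) and flagged in a boolean
mask.  Neighbor order is farthest-upstream .. nearest-upstream,
nearest-downstream .. farthest-downstream, a spatially coherent sequence.
Neighbors always come from *observed* sites only — never from imputed
values — so imputation stays a single pass with no feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .io import GenomeIndex, MethylomeProfile

WINDOW_LEN = 1001
K_PER_SIDE = 25
DIST_SCALE = 25_000.0  # bp; distances are clipped at 1.0 after scaling

_BASE_CHANNEL = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("T"): 3}

PAD_LEVEL = 0.5
PAD_DIST = 1.0


def encode_sequence_batch(genome: GenomeIndex, chrom: str, positions: np.ndarray,
                          window_len: int = WINDOW_LEN) -> np.ndarray:
    """One-hot windows for many positions of one chromosome: (n, w, 4)."""
    if window_len % 2 != 1:
        raise ValueError("window_len must be odd")
    positions = np.asarray(positions, dtype=np.int64)
    cpg = genome.cpg_positions(chrom)
    if not np.isin(positions, cpg).all():
        bad = positions[~np.isin(positions, cpg)][:3]
        raise ValueError(f"positions {bad.tolist()} on {chrom} are not CpG sites")
    seq = genome.sequence(chrom, 1, genome.chrom_len(chrom))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    half = (window_len - 1) // 2
    offs = np.arange(-half, half + 1)
    idx = positions[:, None] + offs[None, :] - 1          # 0-based
    inside = (idx >= 0) & (idx < len(arr))
    base = np.where(inside, arr[np.clip(idx, 0, len(arr) - 1)], 0)
    out = np.zeros((len(positions), window_len, 4), dtype=np.float32)
    for code, ch in _BASE_CHANNEL.items():
        out[..., ch] = (base == code)
    return out


def encode_sequence(genome: GenomeIndex, chrom: str, pos: int,
                    window_len: int = WINDOW_LEN) -> np.ndarray:
    """One-hot window (window_len, 4) for a single CpG site."""
    return encode_sequence_batch(genome, chrom, np.array([pos]), window_len)[0]


@dataclass
class NeighborVector:
    levels: np.ndarray     # (2k,)
    distances: np.ndarray  # (2k,) in [0, 1]
    mask: np.ndarray       # (2k,) True where a real neighbor fills the slot

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.levels, self.distances]).astype(np.float32)


def encode_neighbors_batch(profile: MethylomeProfile, chrom: str,
                           positions: np.ndarray, k_per_side: int = K_PER_SIDE,
                           dist_scale: float = DIST_SCALE,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbor levels/distances/mask for many sites: ((n,2k), (n,2k), (n,2k)).

    The target site itself is always excluded from its own neighbor list.
    """
    positions = np.asarray(positions, dtype=np.int64)
    n, k = len(positions), k_per_side
    levels = np.full((n, 2 * k), PAD_LEVEL, dtype=np.float64)
    dists = np.full((n, 2 * k), PAD_DIST, dtype=np.float64)
    mask = np.zeros((n, 2 * k), dtype=bool)
    if chrom not in profile.by_chrom():
        return levels, dists, mask
    p, lv = profile.by_chrom()[chrom]
    if len(p) == 0:
        return levels, dists, mask
    left_end = np.searchsorted(p, positions, side="left")
    right_start = np.searchsorted(p, positions, side="right")
    # upstream slots, farthest first: indices left_end-k .. left_end-1
    li = left_end[:, None] - np.arange(k, 0, -1)[None, :]
    lvalid = li >= 0
    lidx = np.clip(li, 0, len(p) - 1)
    levels[:, :k] = np.where(lvalid, lv[lidx], PAD_LEVEL)
    dists[:, :k] = np.where(
        lvalid, np.minimum(np.abs(p[lidx] - positions[:, None]) / dist_scale, 1.0),
        PAD_DIST)
    mask[:, :k] = lvalid
    # downstream slots, nearest first: indices right_start .. right_start+k-1
    ri = right_start[:, None] + np.arange(k)[None, :]
    rvalid = ri < len(p)
    ridx = np.clip(ri, 0, len(p) - 1)
    levels[:, k:] = np.where(rvalid, lv[ridx], PAD_LEVEL)
    dists[:, k:] = np.where(
        rvalid, np.minimum(np.abs(p[ridx] - positions[:, None]) / dist_scale, 1.0),
        PAD_DIST)
    mask[:, k:] = rvalid
    return levels, dists, mask


def encode_neighbors(profile: MethylomeProfile, chrom: str, pos: int,
                     k_per_side: int = K_PER_SIDE,
                     dist_scale: float = DIST_SCALE) -> NeighborVector:
    lv, d, m = encode_neighbors_batch(profile, chrom, np.array([pos]),
                                      k_per_side, dist_scale)
    return NeighborVector(levels=lv[0], distances=d[0], mask=m[0])


@dataclass
class EncodedBatch:
    """Arrays for a deterministic (chrom, pos)-ordered set of examples.

    ``neighbors`` has shape (n, m, 4k): per profile, levels then distances.
    ``labels``/``label_mask`` are (n, m); a False mask entry means the
    profile lacks data at that site.
    """

    chrom: np.ndarray          # (n,) unicode
    pos: np.ndarray            # (n,) int64
    seq: np.ndarray            # (n, window_len, 4) float32
    neighbors: np.ndarray      # (n, m, 2 * 2k) float32
    neighbor_mask: np.ndarray  # (n, m, 2k) bool
    labels: np.ndarray         # (n, m) float32
    label_mask: np.ndarray     # (n, m) bool
    task_order: list[str] = field(default_factory=list)

    @property
    def n_examples(self) -> int:
        return len(self.pos)

    @property
    def n_tasks(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx) -> "EncodedBatch":
        return EncodedBatch(self.chrom[idx], self.pos[idx], self.seq[idx],
                            self.neighbors[idx], self.neighbor_mask[idx],
                            self.labels[idx], self.label_mask[idx],
                            list(self.task_order))


def _label_arrays(profile: MethylomeProfile, chrom: str, positions: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    y = np.zeros(len(positions), dtype=np.float64)
    m = np.zeros(len(positions), dtype=bool)
    if chrom in profile.by_chrom():
        p, lv = profile.by_chrom()[chrom]
        i = np.searchsorted(p, positions)
        hit = (i < len(p)) & (p[np.minimum(i, max(len(p) - 1, 0))] == positions)
        y[hit] = lv[i[hit]]
        m[hit] = True
    return y, m


def build_examples(profiles: list[MethylomeProfile], genome: GenomeIndex,
                   site_selector: str = "training",
                   chroms: list[str] | None = None,
                   window_len: int = WINDOW_LEN, k_per_side: int = K_PER_SIDE,
                   dist_scale: float = DIST_SCALE) -> EncodedBatch:
    """Assemble encoded examples over the selected chromosomes.

    ``site_selector='training'`` uses CpG sites covered in at least one
    profile; ``'imputation'`` uses every genome CpG site.  Profiles become
    tasks in alphabetical ``sample_id`` order (recorded in ``task_order``).
    """
    if not profiles:
        raise ValueError("at least one profile required")
    if site_selector not in ("training", "imputation"):
        raise ValueError("site_selector must be 'training' or 'imputation'")
    order = sorted(range(len(profiles)), key=lambda i: profiles[i].sample_id)
    profiles = [profiles[i] for i in order]
    task_order = [p.sample_id for p in profiles]
    chrom_list = sorted(chroms) if chroms is not None else sorted(genome.chroms)

    parts = []
    for chrom in chrom_list:
        cpg = genome.cpg_positions(chrom)
        if site_selector == "training":
            covered = [prof.by_chrom()[chrom][0] for prof in profiles
                       if chrom in prof.by_chrom()]
            if not covered:
                continue
            sites = np.unique(np.concatenate(covered))
            sites = sites[np.isin(sites, cpg)]
        else:
            sites = cpg
        if len(sites) == 0:
            continue
        seq = encode_sequence_batch(genome, chrom, sites, window_len)
        nbr = np.empty((len(sites), len(profiles), 4 * k_per_side),
                       dtype=np.float32)
        nmask = np.empty((len(sites), len(profiles), 2 * k_per_side), dtype=bool)
        labels = np.empty((len(sites), len(profiles)), dtype=np.float32)
        lmask = np.empty((len(sites), len(profiles)), dtype=bool)
        for j, prof in enumerate(profiles):
            lv, d, m = encode_neighbors_batch(prof, chrom, sites, k_per_side,
                                              dist_scale)
            nbr[:, j, :] = np.concatenate([lv, d], axis=1)
            nmask[:, j, :] = m
            y, ym = _label_arrays(prof, chrom, sites)
            labels[:, j] = y
            lmask[:, j] = ym
        parts.append(EncodedBatch(np.array([chrom] * len(sites)), sites, seq,
                                  nbr, nmask, labels, lmask, task_order))
    if not parts:
        import logging
        logging.getLogger(__name__).warning("no examples selected")
        k2 = 2 * k_per_side
        return EncodedBatch(np.array([], dtype=str), np.array([], dtype=np.int64),
                            np.zeros((0, window_len, 4), np.float32),
                            np.zeros((0, len(profiles), 2 * k2), np.float32),
                            np.zeros((0, len(profiles), k2), bool),
                            np.zeros((0, len(profiles)), np.float32),
                            np.zeros((0, len(profiles)), bool), task_order)
    return EncodedBatch(
        np.concatenate([p.chrom for p in parts]),
        np.concatenate([p.pos for p in parts]),
        np.concatenate([p.seq for p in parts]),
        np.concatenate([p.neighbors for p in parts]),
        np.concatenate([p.neighbor_mask for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.label_mask for p in parts]),
        task_order)


def save_batch(batch: EncodedBatch, path) -> None:
    """Persist an encoded batch to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("chrom", data=batch.chrom.astype("S"))
        f.create_dataset("pos", data=batch.pos)
        f.create_dataset("seq", data=batch.seq, compression="gzip")
        f.create_dataset("neighbors", data=batch.neighbors, compression="gzip")
        f.create_dataset("neighbor_mask", data=batch.neighbor_mask,
                         compression="gzip")
        f.create_dataset("labels", data=batch.labels)
        f.create_dataset("label_mask", data=batch.label_mask)
        f.attrs["task_order"] = [t.encode() for t in batch.task_order]


def load_batch(path) -> EncodedBatch:
    with h5py.File(path, "r") as f:
        return EncodedBatch(
            chrom=f["chrom"][:].astype(str),
            pos=f["pos"][:],
            seq=f["seq"][:],
            neighbors=f["neighbors"][:],
            neighbor_mask=f["neighbor_mask"][:],
            labels=f["labels"][:],
            label_mask=f["label_mask"][:],
            task_order=[t.decode() if isinstance(t, bytes) else str(t)
                        for t in f.attrs["task_order"]])
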