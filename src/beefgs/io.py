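"""Flat-file persistence for simulated populations.

A simulation directory contains:

``pedigree.csv``
    id, sire, dam, sex, breed, generation, n_progeny, tbv, y
    (1-based ids; metafounders as negative ids).
``map.tsv``
    chromosome, locus id, position (cM), role (marker/qtl).
``haplotypes.h5`` or ``haplotypes.txt``
    (n, 2, L) 0/1 haplotypes, HDF5 by default or a plain 0/1 matrix with
    two rows per animal (``fmt="text"``).
``genotypes.txt`` (optional export)
    PLINK .raw-like dosage dialect: an id column then 0/1/2 dosages at the
    markers, whitespace-separated, one genotyped animal per row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .population import Population


def save_population(pop: Population, gmap: GenomeMap, out_dir,
                    fmt: str = "hdf5") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = pop.pedigree_frame()
    ped["n_progeny"] = pop.n_progeny
    if pop.tbv is not None:
        ped["tbv"] = pop.tbv
        ped["y"] = pop.y
    ped.to_csv(out / "pedigree.csv", index=False)
    gmap.write_map(out / "map.tsv")
    if fmt == "hdf5":
        import h5py

        with h5py.File(out / "haplotypes.h5", "w") as fh:
            fh.create_dataset("haplotypes", data=pop.haplo,
                              compression="gzip", compression_opts=1)
            fh.attrs["n_metafounders"] = pop.n_metafounders
    elif fmt == "text":
        np.savetxt(out / "haplotypes.txt",
                   pop.haplo.reshape(-1, pop.haplo.shape[-1]), fmt="%d")
    else:
        raise ValueError(f"unknown haplotype format {fmt!r}")


def load_population(in_dir) -> tuple[Population, GenomeMap]:
    src = Path(in_dir)
    ped = pd.read_csv(src / "pedigree.csv")
    gmap = GenomeMap.read_map(src / "map.tsv")
    n_mf = 0
    if (src / "haplotypes.h5").exists():
        import h5py

        with h5py.File(src / "haplotypes.h5", "r") as fh:
            haplo = fh["haplotypes"][...]
            n_mf = int(fh.attrs.get("n_metafounders", 0))
    else:
        flat = np.loadtxt(src / "haplotypes.txt", dtype=np.uint8)
        haplo = flat.reshape(len(ped), 2, -1)

    def decode(col):
        p = ped[col].to_numpy()
        return np.where(p > 0, p - 1, p)

    pop = Population(
        sire=decode("sire").astype(np.int64),
        dam=decode("dam").astype(np.int64),
        sex=np.where(ped["sex"].to_numpy() == "M", 0, 1).astype(np.int8),
        breed=ped["breed"].to_numpy().astype(np.int8),
        gen=ped["generation"].to_numpy().astype(np.int16),
        haplo=haplo,
        n_progeny=ped["n_progeny"].to_numpy().astype(np.int32),
        tbv=ped["tbv"].to_numpy() if "tbv" in ped else None,
        y=ped["y"].to_numpy() if "y" in ped else None,
        n_metafounders=n_mf,
    )
    return pop, gmap


def write_genotypes(pop: Population, gmap: GenomeMap, rows: np.ndarray,
                    path) -> None:
    """Marker dosages of the genotyped animals (id + 0/1/2 columns)."""
    dos = pop.dosage(gmap.marker_idx, rows=rows)
    with open(path, "w") as fh:
        fh.write("id " + " ".join(f"M{j}" for j in range(dos.shape[1])) + "\n")
        for rid, row in zip(np.asarray(rows) + 1, dos):
            fh.write(str(rid) + " " + " ".join(map(str, row)) + "\n")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids (1-based), dosage matrix)."""
    dat = np.loadtxt(path, skiprows=1, dtype=np.int64)
    if dat.ndim == 1:
        dat = dat[None, :]
    return dat[:, 0], dat[:, 1:].astype(np.int16)


def write_id_list(rows: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(rows) + 1, fmt="%d")


def read_id_list(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64).reshape(-1) - 1
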