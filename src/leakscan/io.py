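"""Plain-text and HDF5 readers/writers for the toolkit's data types.

Formats follow breeding-software conventions: whitespace-delimited pedigree
files with 0 for unknown parents, PLINK-.raw-style dosage tables with NA for
missing, a .bim-like TSV marker map, TSV phenotype/scan tables, and HDF5 for
large matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import Pedigree
from .simdata import MISSING, GenotypeMatrix, MarkerMap


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.to_frame().to_csv(path, sep=" ", index=False, header=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep=r"\s+", header=None)
    df.columns = ["animal_id", "sire_id", "dam_id", "generation", "litter_id"][: df.shape[1]]
    return Pedigree.from_frame(df)


def write_marker_map(mmap: MarkerMap, path) -> None:
    mmap.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap.from_frame(pd.read_csv(path, sep="\t"))


def write_genotypes(gm: GenotypeMatrix, path, map_path=None) -> None:
    """PLINK-.raw-style table: header of SNP ids, rows of animal id + dosages."""
    d = gm.dosage.astype(object)
    d[gm.dosage == MISSING] = "NA"
    df = pd.DataFrame(d, columns=list(gm.map.snp_id))
    df.insert(0, "IID", gm.animal_ids)
    df.to_csv(path, sep="\t", index=False)
    if map_path is not None:
        write_marker_map(gm.map, map_path)


def read_genotypes(path, map_path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    mmap = read_marker_map(map_path)
    ids = df["IID"].to_numpy(dtype=np.int64)
    d = df.drop(columns=["IID"]).to_numpy(dtype=np.float64)
    out = np.full(d.shape, MISSING, dtype=np.int8)
    mask = ~np.isnan(d)
    out[mask] = d[mask].astype(np.int8)
    return GenotypeMatrix(out, ids, mmap)


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def genotypes_to_hdf5(gm: GenotypeMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("dosage", data=gm.dosage, compression="gzip")
        f.create_dataset("animal_ids", data=gm.animal_ids)
        f.create_dataset("snp_id", data=np.array(gm.map.snp_id, dtype="S"))
        f.create_dataset("chromosome", data=gm.map.chromosome)
        f.create_dataset("position_bp", data=gm.map.position_bp)
        f.create_dataset("is_md", data=gm.map.is_md)


def genotypes_from_hdf5(path) -> GenotypeMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        mmap = MarkerMap(
            np.array([s.decode() for s in f["snp_id"][:]], dtype=object),
            f["chromosome"][:], f["position_bp"][:], f["is_md"][:],
        )
        return GenotypeMatrix(f["dosage"][:], f["animal_ids"][:], mmap)


def matrix_to_hdf5(values: np.ndarray, animal_ids: np.ndarray, path, name="matrix") -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=values)
        f.create_dataset("animal_ids", data=animal_ids)


def precision_to_triplets_tsv(prec, path) -> None:
    """Upper-triangle triplet TSV (i, j, value), 1-based like breeding tools."""
    r, c, v = prec.to_triplets()
    pd.DataFrame({"i": r + 1, "j": c + 1, "value": v}).to_csv(
        path, sep="\t", index=False, float_format="%.12g")
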