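"""TSV readers/writers for the pipeline's table schemas.

All tables are tab-separated with a header row, UTF-8, '.' decimal and
``NA`` for missing values; no index column is written.

Schemas
-------
bead-level:   array_id, snp_id, bead_index, red_fg, green_fg, red_bg, green_bg
summary:      array_id, snp_id, mean_logR, mean_logG, mean_M, mean_A,
              n_logR, n_logG, n_M, n_A, background_corrected[, normalized]
sample sheet: array_id, sample_id, material, dye, mix_p, replicate, series
genotypes:    snp_id, one column per individual; calls in {AA, AB, BB, NN}
QC report:    array_id, iqr_logR, iqr_logG, flagged
truth manifest: snp_id plus one column per recorded ground-truth field
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_BEAD_DTYPES = {"array_id": str, "snp_id": str, "bead_index": int,
                "red_fg": float, "green_fg": float, "red_bg": float, "green_bg": float}


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True, **kwargs)


def read_bead_table(path) -> pd.DataFrame:
    df = read_tsv(path, dtype=_BEAD_DTYPES)
    missing = set(_BEAD_DTYPES) - set(df.columns)
    if missing:
        raise ValueError(f"bead table {path} lacks columns {sorted(missing)}")
    return df


def read_summary(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"array_id", "snp_id", "mean_logR", "mean_logG", "mean_M", "mean_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary table {path} lacks columns {sorted(missing)}")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"array_id", "sample_id", "material", "dye", "mix_p", "replicate", "series"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    return df


def read_genotypes(path) -> pd.DataFrame:
    df = read_tsv(path).set_index("snp_id")
    bad = set(df.to_numpy().ravel()) - {"AA", "AB", "BB", "NN"}
    if bad:
        raise ValueError(f"genotype table {path} contains invalid calls: {sorted(bad)}")
    return df


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    write_tsv(genotypes.reset_index(), path)
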