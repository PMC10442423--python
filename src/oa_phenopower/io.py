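"""Plain-text and PNG interchange for every pipeline stage."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from oa_phenopower.simulate.genotypes import GenotypePanel
from oa_phenopower.simulate.phantoms import LabeledScan


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_scan(scan: LabeledScan, stem) -> None:
    """Write ``<stem>.png`` (raster) and ``<stem>.mask.png`` (labels)."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(scan.image, mode="L").save(stem.with_suffix(".png"))
    Image.fromarray(scan.mask, mode="L").save(stem.parent / (stem.name + ".mask.png"))


def read_scan(stem, pixel_spacing: float, side: str, subject_id: str = "") -> LabeledScan:
    stem = Path(stem)
    image = np.asarray(Image.open(stem.with_suffix(".png")).convert("L"))
    mask = np.asarray(Image.open(stem.parent / (stem.name + ".mask.png")).convert("L"))
    return LabeledScan(image=image, mask=mask, pixel_spacing=pixel_spacing,
                       side=side, subject_id=subject_id)


def write_panel(panel: GenotypePanel, outdir) -> None:
    """Dosage matrix (subjects x SNPs) and variant map as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dos = pd.DataFrame(panel.dosages, columns=panel.variant_map["SNP"])
    dos.insert(0, "subject", np.arange(panel.n_subjects))
    dos.to_csv(outdir / "dosages.tsv", sep="\t", index=False)
    panel.variant_map.to_csv(outdir / "variants.tsv", sep="\t", index=False)


def read_panel(indir) -> GenotypePanel:
    indir = Path(indir)
    vm = pd.read_csv(indir / "variants.tsv", sep="\t")
    dos = pd.read_csv(indir / "dosages.tsv", sep="\t").drop(columns=["subject"])
    return GenotypePanel(dosages=dos.to_numpy(dtype=np.int8), variant_map=vm)


def sumstats_frame(result) -> pd.DataFrame:
    """PLINK-flavoured summary-statistics table (A1 is the dosage allele)."""
    tab = result.table.copy()
    tab.insert(3, "A1", "A")
    return tab
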