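"""Readers and writers for the pipeline's on-disk formats.

All artifacts are plain text: phenotypes and FC panels as TSV, motion
traces as 6-column whitespace-delimited series, censor masks as
2-column TSV, genotypes as VCF 4.2 with GT fields, biotyping solutions
as TSV plus a JSON provenance sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from biotypeflow.clustering import BiotypeSolution
from biotypeflow.genetics import GenotypePanel
from biotypeflow.motion import CensorMask, MotionTrace, TimeSeriesPanel


# -- phenotypes -------------------------------------------------------------

def write_phenotypes(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- FC panels --------------------------------------------------------------

def write_fc_panel(fc: np.ndarray, subject_ids, path: str | Path) -> None:
    pd.DataFrame(fc, index=pd.Index(subject_ids, name="subject_id")).to_csv(path, sep="\t")


def read_fc_panel(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return df.to_numpy(dtype=float), df.index.to_numpy()


# -- motion and time series -------------------------------------------------

def write_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(path, trace.as_matrix(), fmt="%.8f")


def read_motion_trace(path: str | Path, tr: float = 0.72) -> MotionTrace:
    mat = np.loadtxt(path)
    if mat.ndim != 2 or mat.shape[1] != 6:
        raise ValueError("motion trace file must have 6 columns")
    return MotionTrace(
        dx=mat[:, 0], dy=mat[:, 1], dz=mat[:, 2],
        alpha=mat[:, 3], beta=mat[:, 4], gamma=mat[:, 5], tr=tr,
    )


def write_timeseries(panel: TimeSeriesPanel, path: str | Path) -> None:
    pd.DataFrame(panel.data).to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, tr: float = 0.72) -> TimeSeriesPanel:
    return TimeSeriesPanel(data=pd.read_csv(path, sep="\t").to_numpy(dtype=float), tr=tr)


def write_censor_mask(mask: CensorMask, path: str | Path) -> None:
    df = pd.DataFrame(
        {"frame": np.arange(mask.n_frames),
         "flag": np.where(mask.kept, "kept", "censored")}
    )
    df.to_csv(path, sep="\t", index=False)


def read_censor_mask(path: str | Path) -> CensorMask:
    df = pd.read_csv(path, sep="\t")
    return CensorMask(kept=(df["flag"] == "kept").to_numpy())


# -- feature masks ----------------------------------------------------------

def write_feature_mask(mask, roi_pairs, path: str | Path) -> None:
    iu, ju = roi_pairs
    df = pd.DataFrame(
        {"fc_index": np.arange(len(mask.selected)), "roi_i": iu, "roi_j": ju,
         "selected": mask.selected.astype(int), "selected_by": mask.provenance}
    )
    df.to_csv(path, sep="\t", index=False)


# -- biotype solutions ------------------------------------------------------

def write_solution(solution: BiotypeSolution, subject_ids, out_prefix: str | Path) -> None:
    out_prefix = Path(out_prefix)
    df = pd.DataFrame(
        {"subject_id": subject_ids,
         "cluster": solution.labels,
         "omitted": (solution.labels == -1).astype(int)}
    )
    df.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    sidecar = {
        "k": solution.k, "method": solution.method,
        "vrc_score": solution.vrc_score, "provenance": solution.provenance,
    }
    out_prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


# -- VCF --------------------------------------------------------------------

def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write biallelic genotypes as uncompressed VCF 4.2 with GT fields."""
    ids = (
        panel.subject_ids
        if panel.subject_ids is not None
        else [f"S{i:05d}" for i in range(panel.n_subjects)]
    )
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, ids)) + "\n")
        for j in range(panel.n_snps):
            gts = [
                "./." if np.isnan(d) else gt_map[d] for d in panel.dosages[:, j]
            ]
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\tA\tG\t.\t.\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path, populations: np.ndarray | None = None) -> GenotypePanel:
    """Read a biallelic VCF into a dosage panel (ALT-allele counts)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    dosages, snp_ids, chrom, pos = [], [], [], []
    for var in vcf:
        types = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        d = np.choose(types, [0.0, 1.0, np.nan, 2.0])
        dosages.append(d)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
    if populations is None:
        populations = np.array(["ALL"] * len(samples))
    return GenotypePanel(
        dosages=np.array(dosages).T,
        snp_ids=np.array(snp_ids),
        chrom=np.array(chrom),
        pos=np.array(pos),
        populations=np.asarray(populations),
        subject_ids=samples,
    )
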