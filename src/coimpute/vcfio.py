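"""VCF v4.2 input/output for panels, case samples and imputed targets.

Panels and case samples are written as phased diploid GT records on one
synthetic contig ("1"), minor allele = ALT by construction; reading goes
through cyvcf2 and rejects unphased or multi-allelic records.  A JSON
sidecar (``<path>.json``) can carry the generating :class:`PanelSpec` and
seed for provenance.  Imputed targets are written as a single record with
DS (dosage) and GP (genotype posterior) FORMAT fields, hard calls as GT
with ``./.`` for missing, and the R² quality score in INFO.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
from cyvcf2 import VCF

from .impute import MISSING, ImputedTarget
from .panel import CaseSample, HaplotypePanel, PanelSpec

__all__ = ["write_panel_vcf", "read_panel_vcf", "write_imputed_vcf"]

_CONTIG = "1"
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _open_text(path: Path, mode: str):
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_panel_vcf(
    obj: Union[HaplotypePanel, CaseSample],
    path: Union[str, Path],
    panel: Optional[HaplotypePanel] = None,
    spec: Optional[PanelSpec] = None,
) -> Path:
    """Write a panel or case sample as a phased VCF.

    A panel is written as consecutive haplotype pairs (requires an even
    haplotype count); a case sample needs the generating ``panel`` for site
    coordinates.  When ``spec`` is given, a JSON sidecar records it.
    """
    path = Path(path)
    if isinstance(obj, HaplotypePanel):
        meta = obj
        if obj.n_haplotypes % 2:
            raise ValueError("odd haplotype count cannot be paired into diploid samples")
        haplotypes = obj.alleles
        sample_names = [f"H{i:04d}" for i in range(obj.n_haplotypes // 2)]
    elif isinstance(obj, CaseSample):
        if panel is None:
            raise ValueError("writing a CaseSample requires the generating panel")
        meta = panel
        haplotypes = obj.diplotypes.reshape(obj.n_cases * 2, panel.n_sites)
        sample_names = [f"case{i:04d}" for i in range(obj.n_cases)]
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as a panel VCF")
    if meta.n_sites == 0:
        raise ValueError("empty site list")

    with _open_text(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CONTIG}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_names) + "\n")
        for j in range(meta.n_sites):
            calls = "\t".join(
                f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                for i in range(len(sample_names))
            )
            fh.write(
                f"{_CONTIG}\t{meta.positions[j]}\t{meta.site_ids[j]}\tA\tC\t.\tPASS\t.\tGT\t{calls}\n"
            )

    if spec is not None:
        sidecar = {"panel_spec": dataclasses.asdict(spec), "target_id": "target"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_panel_vcf(path: Union[str, Path], target_id: str = "target") -> HaplotypePanel:
    """Read a phased VCF back into a HaplotypePanel.

    Every record must be biallelic with fully phased, non-missing 0/1
    genotypes.  The target site is identified by its ID (default
    ``"target"``); if absent, the first site is taken as target.
    """
    reader = VCF(str(path))
    columns, positions, ids = [], [], []
    for variant in reader:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} is not supported"
            )
        row = []
        for gt in variant.genotypes:
            alleles, phased = gt[:-1], gt[-1]
            if len(alleles) != 2 or not phased:
                raise ValueError(
                    f"unphased or non-diploid genotype at {variant.CHROM}:{variant.POS}"
                )
            if any(a not in (0, 1) for a in alleles):
                raise ValueError(
                    f"missing or non-biallelic allele at {variant.CHROM}:{variant.POS}"
                )
            row.extend(alleles)
        columns.append(np.array(row, dtype=np.uint8))
        positions.append(variant.POS)
        ids.append(variant.ID if variant.ID is not None else f"site{len(ids)}")
    if not columns:
        raise ValueError("VCF contains no variant records")
    target_index = ids.index(target_id) if target_id in ids else 0
    return HaplotypePanel(
        alleles=np.column_stack(columns),
        positions=np.array(positions),
        site_ids=tuple(ids),
        target_index=target_index,
    )


def write_imputed_vcf(
    imputed: ImputedTarget,
    path: Union[str, Path],
    position: int,
    site_id: str = "target",
) -> Path:
    """Write one imputed target SNP with GT/DS/GP fields and INFO R²."""
    path = Path(path)
    with _open_text(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={_CONTIG}>\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Hard-called genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor-allele dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype posterior">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(f"case{i:04d}" for i in range(imputed.n_cases)) + "\n")
        calls = []
        for i in range(imputed.n_cases):
            gp = ",".join(f"{p:.4f}" for p in imputed.posteriors[i])
            calls.append(
                f"{_GT_STRINGS[int(imputed.hard_calls[i])]}:{imputed.dosages[i]:.4f}:{gp}"
            )
        fh.write(
            f"{_CONTIG}\t{position}\t{site_id}\tA\tC\t.\tPASS\tR2={imputed.r2_score:.6f}"
            f"\tGT:DS:GP\t" + "\t".join(calls) + "\n"
        )
    return path
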