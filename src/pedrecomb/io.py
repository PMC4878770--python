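"""Reading and writing the pipeline's file formats.

VCF 4.2 (FORMAT GT:DP:GQ:AD) via pysam; tab-separated tables for truth,
phased sites and events; BED via :mod:`pedrecomb.intervals`.
Recalibration-tranche failures are carried in INFO flags ``T90FAIL`` /
``T999FAIL`` (absence means the site passed that tranche).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .genome import GenomeLayout
from .simulate import PedigreeSim, SimTruth
from .sites import HAPLOID, MISSING, GenotypeTable


def write_vcf(table: GenotypeTable, path,
              layout: GenomeLayout | None = None) -> None:
    header = pysam.VariantHeader()
    header.add_meta("source", "pedrecomb")
    contigs: dict[str, int] = {}
    if layout is not None:
        for c in layout:
            contigs[c.name] = c.length
    else:
        for chrom, pos in zip(table.chrom, table.pos):
            contigs[str(chrom)] = max(contigs.get(str(chrom), 0), int(pos) + 1)
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta("INFO", items=[("ID", "T90FAIL"), ("Number", "0"),
                                   ("Type", "Flag"),
                                   ("Description", "Failed the 90% tranche")])
    header.add_meta("INFO", items=[("ID", "T999FAIL"), ("Number", "0"),
                                   ("Type", "Flag"),
                                   ("Description", "Failed the 99.9% tranche")])
    for id_, num, typ, desc in [("GT", 1, "String", "Genotype"),
                                ("DP", 1, "Integer", "Read depth"),
                                ("GQ", 1, "Integer", "Genotype quality"),
                                ("AD", "R", "Integer", "Allele depths")]:
        header.add_meta("FORMAT", items=[("ID", id_), ("Number", str(num)),
                                         ("Type", typ), ("Description", desc)])
    for s in table.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(len(table)):
            rec = vcf.new_record(contig=str(table.chrom[i]),
                                 start=int(table.pos[i]) - 1,
                                 alleles=(str(table.ref[i]), str(table.alt[i])))
            if not table.flags["tranche_pass90"][i]:
                rec.info["T90FAIL"] = True
            if not table.flags["tranche_pass999"][i]:
                rec.info["T999FAIL"] = True
            for j, s in enumerate(table.samples):
                g = table.gt[i, j]
                if g[0] == MISSING:
                    gt = (None,)
                elif g[1] == HAPLOID:
                    gt = (int(g[0]),)
                else:
                    gt = (int(g[0]), int(g[1]))
                rec.samples[s]["GT"] = gt
                rec.samples[s]["DP"] = int(table.dp[i, j])
                rec.samples[s]["GQ"] = int(table.gq[i, j])
                rec.samples[s]["AD"] = (int(table.ad[i, j, 0]),
                                        int(table.ad[i, j, 1]))
            vcf.write(rec)


def read_vcf(path) -> GenotypeTable:
    chroms, pos, ref, alt = [], [], [], []
    gts, dps, gqs, ads = [], [], [], []
    bial, t90, t999 = [], [], []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            chroms.append(rec.chrom)
            pos.append(rec.pos)
            ref.append(rec.ref)
            alts = rec.alts or ("N",)
            alt.append(alts[0])
            bial.append(len(alts) == 1)
            t90.append("T90FAIL" not in rec.info)
            t999.append("T999FAIL" not in rec.info)
            grow, drow, qrow, arow = [], [], [], []
            for s in samples:
                sam = rec.samples[s]
                g = sam.get("GT", (None,))
                if g is None or all(a is None for a in g):
                    grow.append((MISSING, MISSING))
                elif len(g) == 1:
                    grow.append((int(g[0]), HAPLOID))
                else:
                    a, b = sorted(int(x) if x is not None else MISSING for x in g)
                    grow.append((a, b))
                drow.append(int(sam.get("DP") or 0))
                qrow.append(int(sam.get("GQ") or 0))
                ad = sam.get("AD") or (0, 0)
                ad = tuple(int(x) if x is not None else 0 for x in ad)
                arow.append((ad + (0, 0))[:2])
            gts.append(grow)
            dps.append(drow)
            gqs.append(qrow)
            ads.append(arow)
    n = len(pos)
    return GenotypeTable(
        samples, chroms, pos, ref, alt,
        np.array(gts, dtype=np.int8).reshape(n, len(samples), 2),
        np.array(dps, dtype=np.int32).reshape(n, len(samples)),
        np.array(gqs, dtype=np.int32).reshape(n, len(samples)),
        np.array(ads, dtype=np.int32).reshape(n, len(samples), 2),
        flags={"biallelic": np.array(bial, dtype=bool),
               "tranche_pass90": np.array(t90, dtype=bool),
               "tranche_pass999": np.array(t999, dtype=bool)},
    )


def truth_co_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame(
        [{"offspring": b.offspring, "side": b.side, "chrom": b.chrom,
          "pos": b.pos} for b in truth.co_breakpoints],
        columns=["offspring", "side", "chrom", "pos"])


def truth_nco_frame(truth: SimTruth) -> pd.DataFrame:
    rows = []
    for t in truth.nco_tracts:
        if t.conversions:
            for c in t.conversions:
                rows.append({"offspring": t.offspring, "side": t.side,
                             "chrom": t.chrom, "tract_start": t.start,
                             "tract_end": t.end, "pos": c.pos,
                             "from_base": c.from_base, "to_base": c.to_base})
        else:
            rows.append({"offspring": t.offspring, "side": t.side,
                         "chrom": t.chrom, "tract_start": t.start,
                         "tract_end": t.end, "pos": pd.NA,
                         "from_base": pd.NA, "to_base": pd.NA})
    return pd.DataFrame(rows, columns=["offspring", "side", "chrom",
                                       "tract_start", "tract_end", "pos",
                                       "from_base", "to_base"])


def write_truth_tables(truth: SimTruth, out_dir) -> tuple[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    co_path = os.path.join(out_dir, "truth_co.tsv")
    nco_path = os.path.join(out_dir, "truth_nco.tsv")
    truth_co_frame(truth).to_csv(co_path, sep="\t", index=False)
    truth_nco_frame(truth).to_csv(nco_path, sep="\t", index=False)
    return co_path, nco_path


def read_linkage_map(path) -> dict[str, float]:
    """Two-column TSV (chrom, cM) -> mapping."""
    df = pd.read_csv(path, sep="\t")
    chrom_col, cm_col = df.columns[0], df.columns[1]
    return dict(zip(df[chrom_col].astype(str), df[cm_col].astype(float)))
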