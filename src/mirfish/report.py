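"""Standard-format output writers for pipeline results.

Pre-miRNAs go out as GFF3 (precursor + mature features, miRBase-style),
isomiR stacks / clusters / arm profiles / family quartiles as TSV, and
the run summary as JSON.  All tables are deterministic for a given
input.
"""

from __future__ import annotations

import json
from pathlib import Path

from mirfish.annotate import Annotation, FamilyRecord
from mirfish.characterize import MirnaCluster, QuartileReport, arm_profile
from mirfish.classify import PreMirna
from mirfish.pipeline import PipelineSummary


def write_gff3(premirnas: list[PreMirna], annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pre, ann in zip(premirnas, annotations):
            s, e = pre.precursor_interval
            attrs = f"ID={pre.id};set={ann.set_label}"
            if ann.ortholog_id:
                attrs += f";ortholog={ann.ortholog_id};family={ann.family}"
            fh.write(
                f"{pre.chrom}\tmirfish\tmiRNA_primary_transcript\t{s + 1}\t{e}\t.\t{pre.strand}\t.\t{attrs}\n"
            )
            for arm, stack in (("5p", pre.isomirs_5p), ("3p", pre.isomirs_3p)):
                for i, iso in enumerate(stack):
                    fh.write(
                        f"{pre.chrom}\tmirfish\tmiRNA\t{s + 1}\t{e}\t{iso.copy_number}\t{pre.strand}\t.\t"
                        f"ID={pre.id}-{arm}-{i + 1};Parent={pre.id};arm={arm};p_value={iso.p_value:.4g}\n"
                    )


def write_isomir_tsv(premirnas: list[PreMirna], annotations: list[Annotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("premirna_id\tset\tchrom\tstrand\tprecursor_start\tprecursor_end\t"
                 "arm\tsequence\tcopy_number\tp_value\tortholog\tfamily\n")
        for pre, ann in zip(premirnas, annotations):
            s, e = pre.precursor_interval
            for arm, stack in (("5p", pre.isomirs_5p), ("3p", pre.isomirs_3p), ("loop", pre.isomirs_loop)):
                for iso in stack:
                    fh.write(
                        f"{pre.id}\t{ann.set_label}\t{pre.chrom}\t{pre.strand}\t{s}\t{e}\t{arm}\t"
                        f"{iso.sequence}\t{iso.copy_number}\t{iso.p_value:.4g}\t"
                        f"{ann.ortholog_id or '.'}\t{ann.family or '.'}\n"
                    )


def write_clusters_tsv(clusters: list[MirnaCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tchrom\tstart\tend\tn_members\tmembers\n")
        for i, c in enumerate(clusters, start=1):
            members = ",".join(m.id for m in c.members)
            fh.write(f"cluster_{i}\t{c.chrom}\t{c.span[0]}\t{c.span[1]}\t{c.size}\t{members}\n")


def write_arm_profiles_tsv(premirnas: list[PreMirna], path: str | Path, dominance_ratio: float = 2.0) -> None:
    with open(path, "w") as fh:
        fh.write("premirna_id\tcategory\tcopies_5p\tcopies_3p\n")
        for pre in premirnas:
            prof = arm_profile(pre, dominance_ratio=dominance_ratio)
            fh.write(f"{pre.id}\t{prof.category}\t{prof.copies_5p}\t{prof.copies_3p}\n")


def write_families_tsv(families: list[FamilyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tconservation_level\texpression_level\n")
        for r in families:
            fh.write(f"{r.family}\t{r.conservation_level}\t{r.expression_level}\n")


def read_families_tsv(path: str | Path) -> list[FamilyRecord]:
    records = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        fam, cons, expr = line.split("\t")
        records.append(FamilyRecord(fam, int(cons), int(expr)))
    return records


def write_quartile_tsv(report: QuartileReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("quarter\tn\tmedian\tq1\tq3\tlo\thi\tmean\n")
        for q in report.quartiles:
            fh.write(
                f"{q['quarter']}\t{q['n']}\t{q['median']:.4f}\t{q['q1']:.4f}\t{q['q3']:.4f}\t"
                f"{q['lo']:.4f}\t{q['hi']:.4f}\t{q['mean']:.4f}\n"
            )
        for t in report.tests:
            fh.write(f"# t-test {t['pair']}: t={t['t']:.4f} p={t['p']:.4g}\n")


def write_summary_json(summary: PipelineSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
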