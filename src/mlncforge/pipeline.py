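"""End-to-end orchestration: classify -> families/conservation -> miRNA ->
targets -> relations (-> expression when Cq data are supplied).

Each stage writes a TSV under the output directory; a machine-readable
manifest records parameters, input checksums and produced files so any
stage can be reproduced byte-identically from the same inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifyParams, classify_set
from .expression import classify_series, cq_matrix, delta_delta_cq, genorm_m, read_cq
from .homology import NucleotideScoring, cluster_families, conservation_screen, relate_mlnc_to_coding
from .mirna import (
    PrecursorCriteria,
    PrecursorRejection,
    evaluate_precursor,
    load_bundled_matures,
    load_matures,
    scan_known_mirnas,
)
from .seq_core import Transcript, find_orfs, read_fasta
from .targets import PenaltySchema, predict_targets

logger = logging.getLogger(__name__)

TIME_BY_SAMPLE = {"t0": 0, "t1": 1, "t5": 5, "t10": 10, "t24": 24}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    unigenes: Path
    out_dir: Path
    proteins: Path | None = None
    annotation_table: Path | None = None
    housekeeping: Path | None = None
    known_ncrna: Path | None = None
    matures: Path | None = None  # default: bundled conserved plant matures
    cq: Path | None = None
    cq_stress: str = "cold"
    cq_reference: str = "ubiquitin"
    cq_calibrator: str = "t0"
    seed: int = 0
    e_cutoff: float = 1e-5
    mfei_region: str = "hairpin"
    max_mismatches: int = 3
    classify_params: ClassifyParams = field(default_factory=ClassifyParams)
    penalty_schema: PenaltySchema = field(default_factory=PenaltySchema)
    precursor_criteria: PrecursorCriteria = field(default_factory=PrecursorCriteria)
    scoring: NucleotideScoring = field(default_factory=NucleotideScoring)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {
            "classify_params": ClassifyParams,
            "penalty_schema": PenaltySchema,
            "precursor_criteria": PrecursorCriteria,
            "scoring": NucleotideScoring,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            elif key in ("unigenes", "out_dir", "proteins", "annotation_table",
                         "housekeeping", "known_ncrna", "matures", "cq"):
                kwargs[key] = Path(value) if value is not None else None
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        if self.unigenes is None:
            raise ValueError("unigenes path is required")
        for name in ("unigenes", "proteins", "annotation_table", "housekeeping",
                     "known_ncrna", "matures", "cq"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"input {name} does not exist: {p}")
        if self.mfei_region not in ("hairpin", "full"):
            raise ValueError("mfei_region must be 'hairpin' or 'full'")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _read_seq_dict(path: Path) -> dict[str, str]:
    return {t.id: t.seq for t in read_fasta(path)}


def _read_protein_fasta(path: Path) -> dict[str, str]:
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out[header.split()[0]] = seq.upper()
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mlnc-forge",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "parameters": {
            "e_cutoff": config.e_cutoff,
            "mfei_region": config.mfei_region,
            "max_mismatches": config.max_mismatches,
            "classify": dataclasses.asdict(config.classify_params),
            "penalty_schema": dataclasses.asdict(config.penalty_schema),
            "precursor_criteria": dataclasses.asdict(config.precursor_criteria),
            "scoring": dataclasses.asdict(config.scoring),
        },
        "inputs": {},
        "outputs": {},
    }
    for name in ("unigenes", "proteins", "annotation_table", "housekeeping",
                 "known_ncrna", "matures", "cq"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    stage = "load"
    try:
        transcripts = read_fasta(config.unigenes)
        proteins = _read_protein_fasta(config.proteins) if config.proteins else None
        annotation = None
        if config.annotation_table:
            annotation = set(
                pd.read_csv(config.annotation_table, sep="\t")["id"].astype(str)
            )
        hk_db = _read_seq_dict(config.housekeeping) if config.housekeeping else None
        matures = (
            load_matures(config.matures) if config.matures else load_bundled_matures()
        )

        stage = "classify"
        table, counts = classify_set(
            transcripts, proteins, annotation, hk_db, config.classify_params
        )
        table.to_csv(out / "classify.tsv", sep="\t", index=False)
        manifest["outputs"]["classify"] = "classify.tsv"
        manifest["class_counts"] = {k: int(v) for k, v in counts.items()}

        by_id = {t.id: t for t in transcripts}
        mlnc_ids = sorted(table.loc[table["class"] == "MLNC_CANDIDATE", "id"])
        mlnc_seqs = {i: by_id[i].seq for i in mlnc_ids}

        stage = "families"
        if mlnc_seqs:
            families, singletons = cluster_families(
                mlnc_seqs, config.e_cutoff, config.scoring
            )
            fam_rows = [
                {"family_id": f.family_id, "member_id": m}
                for f in families
                for m in sorted(f.member_ids)
            ]
            pd.DataFrame(fam_rows, columns=["family_id", "member_id"]).to_csv(
                out / "families.tsv", sep="\t", index=False
            )
            manifest["outputs"]["families"] = "families.tsv"
            manifest["n_families"] = len(families)
            manifest["n_family_members"] = len(fam_rows)

        stage = "conservation"
        if config.known_ncrna and mlnc_seqs:
            db = _read_seq_dict(config.known_ncrna)
            conserved = conservation_screen(mlnc_seqs, db, config.e_cutoff, config.scoring)
            pd.DataFrame(
                [
                    {"mlnc_id": h.query_id, "subject_id": h.subject_id,
                     "evalue": h.evalue, "identity": round(h.identity, 4)}
                    for h in conserved
                ],
                columns=["mlnc_id", "subject_id", "evalue", "identity"],
            ).to_csv(out / "conserved.tsv", sep="\t", index=False)
            manifest["outputs"]["conservation"] = "conserved.tsv"

        stage = "mirna"
        candidates = []
        rejections = []
        for t in transcripts:
            for hit in scan_known_mirnas(t, matures, max_mm=config.max_mismatches):
                result = evaluate_precursor(
                    t, hit, config.precursor_criteria, mfei_region=config.mfei_region
                )
                if isinstance(result, PrecursorRejection):
                    rejections.append(result)
                else:
                    candidates.append((hit, result))
        with open(out / "mirna_candidates.tsv", "w") as fh:
            fh.write(
                "transcript_id\tknown_mirna_id\tmature_seq\tmismatches\tarm\t"
                "precursor_len\tmfe\tgc_percent\tmfei\n"
            )
            for hit, cand in candidates:
                fh.write(
                    f"{cand.transcript_id}\t{cand.known_mirna_id}\t{hit.mature_seq}\t"
                    f"{hit.mismatches}\t{cand.mature_arm}\t{cand.length_nt}\t"
                    f"{cand.mfe:.2f}\t{cand.gc_percent:.2f}\t{cand.mfei:.4f}\n"
                )
        with open(out / "mirna_structures.txt", "w") as fh:
            for hit, cand in candidates:
                fh.write(f">{cand.transcript_id} {cand.known_mirna_id}\n")
                fh.write(cand.precursor_seq + "\n" + cand.structure + "\n")
        manifest["outputs"]["mirna"] = "mirna_candidates.tsv"
        manifest["n_mirna_candidates"] = len(candidates)

        stage = "targets"
        mature_queries = {
            f"{cand.transcript_id}|{cand.known_mirna_id}": hit.mature_seq
            for hit, cand in candidates
        }
        precursor_of = {
            f"{cand.transcript_id}|{cand.known_mirna_id}": cand.transcript_id
            for hit, cand in candidates
        }
        target_hits = []
        for qid, mseq in sorted(mature_queries.items()):
            scan_set = [t for t in transcripts if t.id != precursor_of[qid]]
            for h in predict_targets({qid: mseq}, scan_set, config.penalty_schema):
                target_hits.append(h)
        with open(out / "targets.tsv", "w") as fh:
            fh.write("mirna_id\ttranscript_id\tstart1\tend1\tpenalty\n")
            for h in target_hits:
                fh.write(
                    f"{h.mirna_id}\t{h.transcript_id}\t{h.t_start + 1}\t{h.t_end}\t"
                    f"{h.penalty:g}\n"
                )
        with open(out / "target_duplexes.txt", "w") as fh:
            for h in target_hits:
                fh.write(f">{h.mirna_id} -> {h.transcript_id}:{h.t_start + 1}-{h.t_end}"
                         f" penalty={h.penalty:g}\n")
                fh.write("miRNA  5' " + h.duplex[0] + " 3'\n")
                fh.write("          " + h.duplex[1] + "\n")
                fh.write("target 3' " + h.duplex[2] + " 5'\n")
        manifest["outputs"]["targets"] = "targets.tsv"
        manifest["n_targets"] = len(target_hits)

        stage = "relations"
        coding_ids = table.loc[
            table["class"].isin(["ANNOTATED_CODING", "NOVEL_CODING"]), "id"
        ]
        coding = []
        for cid in sorted(coding_ids):
            orfs = find_orfs(by_id[cid])
            coding.append((by_id[cid], orfs[0] if orfs else None))
        relations = relate_mlnc_to_coding(
            mlnc_seqs, coding, config.e_cutoff, config.scoring
        )
        pd.DataFrame(
            [
                {
                    "mlnc_id": r.mlnc_id, "coding_id": r.coding_id,
                    "orientation": r.orientation, "region": r.region,
                    "identity": round(r.identity, 4),
                    "q_start1": r.q_start + 1, "q_end1": r.q_end,
                    "s_start1": r.s_start + 1, "s_end1": r.s_end,
                }
                for r in relations
            ],
            columns=["mlnc_id", "coding_id", "orientation", "region", "identity",
                     "q_start1", "q_end1", "s_start1", "s_end1"],
        ).to_csv(out / "relations.tsv", sep="\t", index=False)
        manifest["outputs"]["relations"] = "relations.tsv"
        manifest["n_relations"] = len(relations)

        if config.cq:
            stage = "expression"
            cq_long = read_cq(config.cq)
            cq = cq_matrix(cq_long)
            stability = genorm_m(cq, ["ubiquitin", "actin", "rRNA18S"]
                                 if {"ubiquitin", "actin", "rRNA18S"} <= set(cq.index)
                                 else None)
            stability.rename_axis("gene").reset_index().to_csv(
                out / "stability.tsv", sep="\t", index=False
            )
            fold_rows = []
            resp_rows = []
            for gene in sorted(cq.index):
                if gene == config.cq_reference:
                    continue
                folds = delta_delta_cq(cq, gene, config.cq_reference, config.cq_calibrator)
                series = pd.Series(
                    {TIME_BY_SAMPLE[s]: folds[s] for s in folds.index if s in TIME_BY_SAMPLE}
                ).sort_index()
                for tp, v in series.items():
                    fold_rows.append({"gene": gene, "time_h": tp, "fold": v})
                try:
                    rc = classify_series(gene, series, config.cq_stress)
                    resp_rows.append(
                        {"gene": gene, "stress": rc.stress,
                         "responsive": rc.responsive, "subclass": rc.subclass}
                    )
                except ValueError:
                    pass
            pd.DataFrame(fold_rows).to_csv(out / "folds.tsv", sep="\t", index=False)
            pd.DataFrame(resp_rows).to_csv(out / "response.tsv", sep="\t", index=False)
            manifest["outputs"]["expression"] = "response.tsv"

        stage = "summary"
        with open(out / "summary.tsv", "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"n_transcripts\t{len(transcripts)}\n")
            for k, v in manifest["class_counts"].items():
                fh.write(f"count_{k}\t{v}\n")
            for key in ("n_families", "n_mirna_candidates", "n_targets", "n_relations"):
                if key in manifest:
                    fh.write(f"{key}\t{manifest[key]}\n")
        manifest["outputs"]["summary"] = "summary.tsv"
    except Exception as exc:
        (out / f"FAILED_{stage}").write_text(repr(exc) + "\n")
        raise PipelineError(stage, exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
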