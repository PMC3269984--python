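"""Synthetic transcriptome and qPCR generator with planted ground truth.

Emulates the composition of a 454-style unigene set so every pipeline
stage is testable without downloads: protein-coding transcripts with a
planted >= 100-aa ORF and UTRs (half of them with their protein in the
reference set, the rest "novel"), mRNA-like non-coding transcripts that
verifiably lack any 100-aa ORF, homologous mlncRNA families (mutated
copies of a seed sequence, 2-8 members), housekeeping ncRNA transcripts
copying a bundled reference, hairpin precursors embedding bundled mature
miRNAs (verified to pass the precursor criteria before emission), target
transcripts carrying duplex sites with exact planted penalties, and short
(< 300 bp) transcripts.  Cq time-courses (0/1/5/10/24 h, triplicate wells)
carry planted stress-response subclasses.

Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import mirna as mirna_mod
from . import seq_core
from .mirna import MatureMirnaHit, PrecursorCriteria, evaluate_precursor, scan_known_mirnas
from .seq_core import Transcript, find_orfs, max_orf_aa, reverse_complement
from .targets import PenaltySchema, score_duplex

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
_NON_STOP_CODONS = sorted(
    c
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
    if c not in seq_core.STOP_CODONS
)

COLD_TEMPLATES = {
    "A": (1.0, 1.0, 1.0, 1.0, 1.0),
    "B": (1.0, 0.25, 0.2, 0.2, 0.45),
    "C": (1.0, 5.0, 2.5, 1.2, 0.5),
    "C5": (1.0, 1.2, 5.0, 2.0, 0.6),
    "C10": (1.0, 1.1, 1.8, 5.0, 0.8),
}
DEHYDRATION_TEMPLATES = {
    "I": (1.0, 1.05, 1.0, 1.1, 3.0),
    "II": (1.0, 0.25, 0.3, 0.3, 0.5),
    "III": (1.0, 4.0, 1.0, 0.6, 0.4),
}
SAMPLE_NAMES = ("t0", "t1", "t5", "t10", "t24")


class DesignError(ValueError):
    pass


@dataclass
class SynthDesign:
    """Study-condition parameters for the generator."""

    seed: int = 7
    n_coding: int = 60
    n_mlnc: int = 70  # singleton mlncRNA candidates
    n_short: int = 25
    n_hk: int = 5
    n_precursors: int = 8
    n_targets: int = 10
    family_sizes: tuple[int, ...] = (2, 3, 4, 5, 8)
    mutation_rate: float = 0.05
    gc_range: tuple[float, float] = (0.35, 0.55)
    cq_noise_sd: float = 0.2
    annotated_fraction: float = 0.5
    mlnc_len_range: tuple[int, int] = (300, 700)
    coding_orf_aa_range: tuple[int, int] = (100, 200)
    utr_len_range: tuple[int, int] = (50, 150)
    short_len_range: tuple[int, int] = (100, 299)
    planted_penalties: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 0.0, 2.0, 3.0)
    n_response_genes: int = 30

    def validate(self) -> None:
        counts = (
            self.n_coding, self.n_mlnc, self.n_short, self.n_hk,
            self.n_precursors, self.n_targets,
        )
        if any(c < 0 for c in counts):
            raise DesignError("counts must be non-negative")
        if any(not (2 <= s <= 8) for s in self.family_sizes):
            raise DesignError("family sizes must be between 2 and 8")
        if not (0.0 <= self.mutation_rate <= 0.3):
            raise DesignError("mutation_rate must be in [0, 0.3]")
        if self.mlnc_len_range[0] < 300:
            raise DesignError("mlncRNA transcripts must be at least 300 bp")
        if self.short_len_range[1] >= 300:
            raise DesignError("short transcripts must be under 300 bp")
        if not (0.0 < self.gc_range[0] <= self.gc_range[1] < 1.0):
            raise DesignError("invalid gc_range")


@dataclass
class SynthTranscriptome:
    transcripts: list[Transcript]
    truth: pd.DataFrame  # id, planted_class, detail
    proteins: dict[str, str]
    hk_db: dict[str, str]
    matures: dict[str, str]
    family_truth: dict[str, str]  # member id -> family label
    precursor_truth: pd.DataFrame  # transcript_id, mature_id, start, strand
    target_truth: pd.DataFrame  # mirna_id, transcript_id, start, penalty


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _gc(rng: np.random.Generator, design: SynthDesign) -> float:
    lo, hi = design.gc_range
    return float(rng.uniform(lo, hi))


def _has_long_orf(seq: str, cutoff_aa: int = 100) -> bool:
    t = Transcript(id="tmp", seq=seq, source="synthetic")
    return max_orf_aa(find_orfs(t), include_partials=True) >= cutoff_aa


def _noncoding_seq(rng, design, length: int, max_tries: int = 200) -> str:
    """Random sequence guaranteed (by rejection) to lack a 100-aa ORF."""
    for _ in range(max_tries):
        s = _random_seq(rng, length, _gc(rng, design))
        if not _has_long_orf(s):
            return s
    raise DesignError("could not draw an ORF-free sequence")  # pragma: no cover


def _mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alternatives = [b for b in "ACGT" if b != out[i]]
            out[i] = alternatives[int(rng.integers(3))]
    return "".join(out)


def _load_bundled_hk() -> dict[str, str]:
    with resources.as_file(
        resources.files("mlncforge.data").joinpath("housekeeping_synthetic.fasta")
    ) as p:
        return {t.id: t.seq for t in seq_core.read_fasta(p, source="synthetic")}


def _coding_transcript(rng, design) -> tuple[str, str]:
    """(sequence, protein) with a complete planted ORF and UTRs."""
    aa_len = int(rng.integers(design.coding_orf_aa_range[0], design.coding_orf_aa_range[1] + 1))
    codons = [_NON_STOP_CODONS[int(k)] for k in rng.integers(0, 61, size=aa_len - 1)]
    orf = "ATG" + "".join(codons) + "TAA"
    utr5 = _random_seq(rng, int(rng.integers(*design.utr_len_range)), _gc(rng, design))
    utr3 = _random_seq(rng, int(rng.integers(*design.utr_len_range)), _gc(rng, design))
    from Bio.Seq import Seq

    protein = str(Seq(orf[:-3]).translate())
    return utr5 + orf + utr3, protein


def _plant_gu(rng, mature: str, star: str, n_gu: int) -> str:
    """Convert up to n_gu Watson-Crick pairs of the duplex into G:U wobbles."""
    star_l = list(star)
    L = len(mature)
    eligible = [i for i, b in enumerate(mature) if b in "GT"]
    rng.shuffle(eligible)
    for i in eligible[:n_gu]:
        j = L - 1 - i  # star index paired with mature position i
        star_l[j] = "T" if mature[i] == "G" else "G"
    return "".join(star_l)


def _precursor_transcript(
    rng, design, mature_id: str, mature: str, criteria: PrecursorCriteria
) -> tuple[str, int, str] | None:
    """Transcript embedding a hairpin that passes the precursor criteria.

    Returns (sequence, mature_start, strand) or None if retries exhausted.
    """
    L = len(mature)
    for _ in range(25):
        loop = _random_seq(rng, int(rng.integers(4, 9)), 0.3)
        star = _plant_gu(rng, mature, reverse_complement(mature), int(rng.integers(0, 3)))
        hairpin = mature + loop + star
        total = int(rng.integers(300, 451))
        flank_total = max(total - len(hairpin), 40)
        left = int(rng.integers(15, flank_total - 14))
        seq = (
            _random_seq(rng, left, _gc(rng, design))
            + hairpin
            + _random_seq(rng, flank_total - left, _gc(rng, design))
        )
        if _has_long_orf(seq):
            continue
        t = Transcript(id="tmp", seq=seq, source="synthetic")
        hit = MatureMirnaHit(
            transcript_id="tmp", known_mirna_id=mature_id,
            mature_seq=seq_core.as_rna(mature), mismatches=0,
            strand="+", start=left, end=left + L,
        )
        result = evaluate_precursor(t, hit, criteria)
        if not isinstance(result, mirna_mod.PrecursorRejection):
            return seq, left, "+"
    return None


_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _plant_site(rng, mirna: str, penalty: float, schema: PenaltySchema) -> str:
    """Write a target site (transcript 5'->3') with an exact planted penalty.

    Works backwards from the schema: the perfect site is the reverse
    complement of the miRNA; imperfections are placed at non-seed miRNA
    positions (mismatch 1.0, G:U 0.5 there), so any penalty on a 0.5 grid
    up to the cutoff is constructible.
    """
    m = seq_core.normalize_seq(mirna)
    L = len(m)
    site = list(reverse_complement(m))
    non_seed = [i for i in range(L) if not (schema.seed_start <= i + 1 <= schema.seed_end)]
    rng.shuffle(non_seed)
    remaining = penalty
    for i in non_seed:
        if remaining <= 0:
            break
        j = L - 1 - i  # site index opposite miRNA position i
        if remaining >= schema.mismatch_penalty:
            # mismatch: neither WC nor G:U partner of m[i]
            partners = {_WC[m[i]]}
            if m[i] == "G":
                partners.add("T")
            if m[i] == "T":
                partners.add("G")
            choices = [b for b in "ACGT" if b not in partners]
            site[j] = choices[int(rng.integers(len(choices)))]
            remaining -= schema.mismatch_penalty
        elif remaining >= schema.gu_penalty and m[i] in "GT":
            site[j] = "T" if m[i] == "G" else "G"
            remaining -= schema.gu_penalty
    if remaining > 1e-9:
        raise DesignError(f"cannot decompose penalty {penalty} at non-seed positions")
    return "".join(site)


def generate_transcriptome(design: SynthDesign | None = None) -> SynthTranscriptome:
    """Generate the planted transcriptome; reproducible for a fixed seed."""
    design = design or SynthDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)
    hk_refs = _load_bundled_hk()
    matures = mirna_mod.load_bundled_matures()
    criteria = PrecursorCriteria()
    schema = PenaltySchema()

    transcripts: list[Transcript] = []
    truth_rows: list[dict] = []
    proteins: dict[str, str] = {}
    family_truth: dict[str, str] = {}
    precursor_rows: list[dict] = []
    target_rows: list[dict] = []

    def add(tid: str, seq: str, planted: str, detail: str = "") -> None:
        transcripts.append(Transcript(id=tid, seq=seq, source="synthetic"))
        truth_rows.append(
            {"id": tid, "planted_class": planted, "length": len(seq), "detail": detail}
        )

    n_annot = int(round(design.n_coding * design.annotated_fraction))
    for k in range(design.n_coding):
        seq, protein = _coding_transcript(rng, design)
        tid = f"synthCOD{k + 1:04d}"
        if k < n_annot:
            proteins[f"synthPROT{k + 1:04d}"] = protein
            add(tid, seq, "ANNOTATED_CODING")
        else:
            add(tid, seq, "NOVEL_CODING")

    for k in range(design.n_mlnc):
        length = int(rng.integers(design.mlnc_len_range[0], design.mlnc_len_range[1] + 1))
        add(f"synthMLNC{k + 1:04d}", _noncoding_seq(rng, design, length), "MLNC_CANDIDATE")

    for fam_idx, size in enumerate(design.family_sizes):
        label = f"synthFAM{fam_idx + 1:02d}"
        length = int(rng.integers(350, 601))
        seed_seq = _noncoding_seq(rng, design, length)
        for m_idx in range(size):
            for _ in range(50):
                member = _mutate(rng, seed_seq, design.mutation_rate) if m_idx else seed_seq
                if not _has_long_orf(member):
                    break
            tid = f"{label}M{m_idx + 1}"
            family_truth[tid] = label
            add(tid, member, "MLNC_CANDIDATE", detail=label)

    for k in range(design.n_short):
        length = int(rng.integers(design.short_len_range[0], design.short_len_range[1] + 1))
        add(f"synthSHORT{k + 1:04d}", _random_seq(rng, length, _gc(rng, design)),
            "SHORT_UNANNOTATED")

    hk_ids = sorted(hk_refs)
    for k in range(design.n_hk):
        ref_id = hk_ids[k % len(hk_ids)]
        ref = hk_refs[ref_id]
        for _ in range(100):
            pad = max(320 - len(ref), 60)
            left = int(rng.integers(10, pad - 9))
            seq = (
                _random_seq(rng, left, _gc(rng, design))
                + ref
                + _random_seq(rng, pad - left, _gc(rng, design))
            )
            if not _has_long_orf(seq):
                break
        add(f"synthHKT{k + 1:04d}", seq, "HOUSEKEEPING_NPCRNA", detail=ref_id)

    mature_ids = sorted(matures)
    for k in range(design.n_precursors):
        mid = mature_ids[k % len(mature_ids)]
        made = _precursor_transcript(rng, design, mid, matures[mid], criteria)
        if made is None:
            raise DesignError(f"failed to build an accepted precursor for {mid}")
        seq, start, strand = made
        tid = f"synthPRE{k + 1:04d}"
        add(tid, seq, "MLNC_CANDIDATE", detail=f"precursor:{mid}")
        precursor_rows.append(
            {"transcript_id": tid, "mature_id": mid, "start": start,
             "end": start + len(matures[mid]), "strand": strand}
        )

    for k in range(design.n_targets):
        mid = mature_ids[k % len(mature_ids)]
        penalty = design.planted_penalties[k % len(design.planted_penalties)]
        site = _plant_site(rng, matures[mid], penalty, schema)
        for _ in range(50):
            length = int(rng.integers(300, 601))
            backbone = _noncoding_seq(rng, design, length)
            pos = int(rng.integers(20, length - len(site) - 20))
            seq = backbone[:pos] + site + backbone[pos + len(site):]
            if _has_long_orf(seq):
                continue
            got, _duplex = score_duplex(matures[mid], site, schema)
            if abs(got - penalty) < 1e-9:
                break
        else:  # pragma: no cover - defensive
            raise DesignError("failed to plant a target site")
        tid = f"synthTGT{k + 1:04d}"
        add(tid, seq, "MLNC_CANDIDATE", detail=f"target:{mid}:{penalty}")
        target_rows.append(
            {"mirna_id": mid, "transcript_id": tid, "start": pos,
             "end": pos + len(site), "penalty": penalty}
        )

    truth = pd.DataFrame(truth_rows)
    return SynthTranscriptome(
        transcripts=transcripts,
        truth=truth,
        proteins=proteins,
        hk_db=dict(hk_refs),
        matures=matures,
        family_truth=family_truth,
        precursor_truth=pd.DataFrame(precursor_rows),
        target_truth=pd.DataFrame(target_rows),
    )


def generate_hairpin_decoys(
    synth: SynthTranscriptome, n_per_precursor: int = 3, seed: int = 99
) -> list[tuple[Transcript, MatureMirnaHit]]:
    """Shuffled-hairpin decoys: the mature stays in place, everything
    around it is permuted, destroying the star arm."""
    rng = np.random.default_rng(seed)
    by_id = {t.id: t for t in synth.transcripts}
    decoys = []
    for row in synth.precursor_truth.itertuples():
        t = by_id[row.transcript_id]
        mature = t.seq[row.start : row.end]
        context = list(t.seq[: row.start] + t.seq[row.end :])
        for k in range(n_per_precursor):
            rng.shuffle(context)
            shuffled = "".join(context)
            seq = shuffled[: row.start] + mature + shuffled[row.start :]
            dt = Transcript(id=f"{t.id}_decoy{k + 1}", seq=seq, source="synthetic")
            hit = MatureMirnaHit(
                transcript_id=dt.id, known_mirna_id=row.mature_id,
                mature_seq=seq_core.as_rna(mature), mismatches=0,
                strand="+", start=row.start, end=row.end,
            )
            decoys.append((dt, hit))
    return decoys


def generate_cq(
    design: SynthDesign | None = None, stress: str = "cold", n_genes: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cq time-course (triplicate wells) with planted response subclasses.

    Returns (long-format Cq frame, truth frame with gene -> subclass).
    The reference candidates are a stable ubiquitin analogue and two less
    stable candidates (actin- and 18S-like), mirroring the usual qPCR
    reference panel.
    """
    design = design or SynthDesign()
    design.validate()
    templates = COLD_TEMPLATES if stress == "cold" else DEHYDRATION_TEMPLATES
    if stress not in ("cold", "dehydration"):
        raise ValueError("stress must be 'cold' or 'dehydration'")
    rng = np.random.default_rng(design.seed + (0 if stress == "cold" else 1))
    n = n_genes if n_genes is not None else design.n_response_genes
    labels = sorted(templates)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    sd = design.cq_noise_sd

    def emit(gene: str, clean_by_sample: dict[str, float]) -> None:
        for sample in SAMPLE_NAMES:
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "gene": gene,
                        "sample": sample,
                        "replicate": rep,
                        "cq": round(clean_by_sample[sample] + rng.normal(0.0, sd), 4),
                    }
                )

    emit("ubiquitin", {s: 19.0 for s in SAMPLE_NAMES})
    actin_shift = {s: 21.0 + rng.normal(0.0, 0.8) for s in SAMPLE_NAMES}
    emit("actin", actin_shift)
    rrna_shift = {s: 10.0 + rng.normal(0.0, 1.5) for s in SAMPLE_NAMES}
    emit("rRNA18S", rrna_shift)

    for k in range(n):
        label = labels[k % len(labels)]
        template = templates[label]
        gene = f"g{k + 1:04d}"
        base = float(rng.uniform(22.0, 30.0))
        clean = {
            s: base - float(np.log2(template[i])) for i, s in enumerate(SAMPLE_NAMES)
        }
        emit(gene, clean)
        subclass = "C" if label.startswith("C") else label
        truth_rows.append({"gene": gene, "stress": stress, "subclass": subclass})

    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def write_transcriptome(synth: SynthTranscriptome, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA/TSV artefacts; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "unigenes": out / "unigenes.fasta",
        "proteins": out / "proteins.fasta",
        "hk": out / "housekeeping.fasta",
        "matures": out / "mature_mirnas.fasta",
        "truth": out / "truth.tsv",
        "precursor_truth": out / "precursor_truth.tsv",
        "target_truth": out / "target_truth.tsv",
    }
    seq_core.write_fasta(synth.transcripts, paths["unigenes"])
    with open(paths["proteins"], "w") as fh:  # amino-acid records: plain writer
        for pid in sorted(synth.proteins):
            fh.write(f">{pid}\n")
            pseq = synth.proteins[pid]
            for i in range(0, len(pseq), 60):
                fh.write(pseq[i : i + 60] + "\n")
    seq_core.write_fasta(
        [Transcript(id=k, seq=v, source="synthetic") for k, v in sorted(synth.hk_db.items())],
        paths["hk"],
    )
    seq_core.write_fasta(
        [Transcript(id=k, seq=v, source="synthetic") for k, v in sorted(synth.matures.items())],
        paths["matures"],
    )
    synth.truth.to_csv(paths["truth"], sep="\t", index=False)
    synth.precursor_truth.to_csv(paths["precursor_truth"], sep="\t", index=False)
    synth.target_truth.to_csv(paths["target_truth"], sep="\t", index=False)
    return paths
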