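"""Two-library small-RNA dataset simulator with planted ground truth.

Generates raw FASTQ libraries, the three reference FASTA files
(mature miRNAs, labelled ncRNAs, transcripts) and a per-read truth
manifest, so the whole pipeline can be exercised end-to-end with no
external data.  Planted material: hairpin precursors embedded in
transcripts, mature miRNAs excised from one arm with length-variant
isoforms and low-abundance star strands, ncRNA fragments, adapter
artifacts, polyA reads and short inserts, and per-tag counts drawn from
a two-condition Poisson model with known fold changes.

All randomness flows from ``SimulationConfig.seed`` through a single
``numpy`` generator: the same seed yields byte-identical output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._seq import revcomp
from .preprocessing import DEFAULT_ADAPTER_3P, DEFAULT_ADAPTER_5P

__all__ = [
    "SimulationConfig",
    "Hairpin",
    "HairpinRecord",
    "GroundTruth",
    "SimulatedDataset",
    "build_hairpin",
    "simulate_libraries",
]

BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONTAMINANT_KEYS = (
    "adaptor3_null",
    "insert_null",
    "adaptor5_contaminant",
    "short",
    "polyA",
    "ncRNA_fragment",
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_hairpins: int = 200
    conserved_fraction: float = 0.5
    n_ncrna_refs: int = 40
    n_transcripts: int = 260
    transcript_len_range: tuple[int, int] = (400, 700)
    hairpin_stem_len_range: tuple[int, int] = (24, 35)
    loop_len_range: tuple[int, int] = (4, 15)
    mature_len_dist: dict[int, float] = field(
        default_factory=lambda: {20: 0.10, 21: 0.55, 22: 0.20, 23: 0.15}
    )
    isoform_rate: float = 0.15
    star_fraction: float = 0.15
    five_prime_u_prob: float = 0.7
    adapter_seq: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "adaptor3_null": 0.010,
            "insert_null": 0.005,
            "adaptor5_contaminant": 0.010,
            "short": 0.010,
            "polyA": 0.005,
            "ncRNA_fragment": 0.060,
        }
    )
    de_fraction: float = 0.3
    de_log2fc_range: tuple[float, float] = (2.0, 5.0)
    library_depths: tuple[int, int] = (1_000_000, 1_000_000)
    abundance_sigma: float = 1.5
    target_site_fraction: float = 0.2
    wobble_prob: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    @property
    def clean_fraction(self) -> float:
        return 1.0 - sum(self.contaminant_fractions.values())

    def validate(self) -> None:
        unknown = set(self.contaminant_fractions) - set(CONTAMINANT_KEYS)
        if unknown:
            raise ValueError(f"unknown contaminant categories: {sorted(unknown)}")
        if any(v < 0 for v in self.contaminant_fractions.values()):
            raise ValueError("contaminant fractions must be non-negative")
        if self.clean_fraction < -1e-9:
            raise ValueError("contaminant fractions sum to more than 1")
        if abs(sum(self.contaminant_fractions.values()) + self.clean_fraction - 1.0) > 1e-9:
            raise ValueError("fractions do not sum to 1")
        if not math.isclose(sum(self.mature_len_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("mature_len_dist must sum to 1")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        if not 0 <= self.star_fraction < 1:
            raise ValueError("star_fraction must be in [0, 1)")
        lo, hi = self.hairpin_stem_len_range
        if lo > hi or lo < max(self.mature_len_dist):
            raise ValueError(
                "hairpin stem length range must cover the longest mature length"
            )


@dataclass
class Hairpin:
    """A constructed precursor with its planted annotation."""

    sequence: str
    structure: str
    mature_interval: tuple[int, int]  # precursor coords, half-open
    star_interval: tuple[int, int] | None
    arm: str = "5p"

    @property
    def mature(self) -> str:
        return self.sequence[slice(*self.mature_interval)]

    @property
    def star(self) -> str | None:
        if self.star_interval is None:
            return None
        return self.sequence[slice(*self.star_interval)]


@dataclass
class HairpinRecord:
    mirna_id: str
    kind: str  # "conserved" | "novel"
    precursor: str
    structure: str
    mature: str
    mature_interval: tuple[int, int]
    star: str | None
    star_interval: tuple[int, int] | None
    arm: str
    host_transcript: str
    offset: int
    family: str | None = None


@dataclass
class GroundTruth:
    hairpins: list[HairpinRecord]
    tag_labels: dict[str, str]
    tag_mirna: dict[str, str]
    true_log2fc: dict[str, float]
    expected_counts: dict[tuple[str, int], float]
    actual_counts: dict[tuple[str, int], int]
    target_sites: list[tuple[str, str, int, int]]

    def validate(self, transcripts: dict[str, str]) -> None:
        for h in self.hairpins:
            a, b = h.mature_interval
            if h.precursor[a:b] != h.mature:
                raise AssertionError("mature not at its recorded coordinates")
            host = transcripts[h.host_transcript]
            if host[h.offset : h.offset + len(h.precursor)] != h.precursor:
                raise AssertionError("precursor not at its recorded offset")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    fastq: tuple[Path, Path]
    mature_reference: Path
    ncrna_reference: Path
    transcripts_fasta: Path
    manifest: Path
    ground_truth_json: Path
    truth: GroundTruth
    transcripts: dict[str, str]


def _rand_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(0, len(letters), length)])


def build_hairpin(
    stem_len: int,
    loop_len: int,
    bulges: int,
    rng: np.random.Generator,
    *,
    mature_len: int = 21,
    five_prime_u_prob: float = 0.7,
    wobble_prob: float = 0.05,
    mature: str | None = None,
) -> Hairpin:
    """Construct a stem-loop precursor with a planted mature on the 5' arm.

    The 3' arm is the reverse complement of the 5' arm (occasional G:U
    wobbles outside the mature duplex); ``bulges`` unpaired nucleotides
    are inserted at stem columns away from the mature/star duplex.  The
    star interval records the strand pairing the mature with 2-nt 3'
    overhangs.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be at least 3")
    if mature is not None:
        mature_len = len(mature)
    if stem_len < mature_len:
        raise ValueError("stem_len shorter than the mature length")
    if mature is None:
        first = "T" if rng.random() < five_prime_u_prob else _rand_seq(rng, 1)
        mature = first + _rand_seq(rng, mature_len - 1)
    m0 = min(2, stem_len - mature_len)
    if stem_len - mature_len > 2:
        m0 = 2 + int(rng.integers(0, stem_len - mature_len - 1))

    arm5 = list(_rand_seq(rng, stem_len))
    arm5[m0 : m0 + mature_len] = list(mature)
    arm3 = [_COMP[b] for b in arm5]  # arm3[c] pairs arm5[c]
    protected = set(range(max(0, m0 - 3), min(stem_len, m0 + mature_len + 2)))
    for c in range(stem_len):
        if c in protected:
            continue
        if arm5[c] in "GT" and rng.random() < wobble_prob:
            arm3[c] = "T" if arm5[c] == "G" else "G"  # G:U wobble pair

    allowed = [c for c in range(stem_len) if c not in protected]
    n_bulges = min(bulges, len(allowed))
    bulge_cols = set(
        int(c) for c in rng.choice(allowed, size=n_bulges, replace=False)
    ) if n_bulges else set()
    bulge_arm = {c: ("5" if rng.random() < 0.5 else "3") for c in sorted(bulge_cols)}

    seq: list[str] = []
    struct: list[str] = []
    pos5: dict[int, int] = {}
    for c in range(stem_len):
        if c in bulge_cols and bulge_arm[c] == "5":
            seq.append(_rand_seq(rng, 1, "AC"))
            struct.append(".")
        pos5[c] = len(seq)
        seq.append(arm5[c])
        struct.append("(")
    loop = _rand_seq(rng, loop_len, "AC")
    seq.extend(loop)
    struct.extend("." * loop_len)
    pos3: dict[int, int] = {}
    for c in range(stem_len - 1, -1, -1):
        if c in bulge_cols and bulge_arm[c] == "3":
            seq.append(_rand_seq(rng, 1, "AC"))
            struct.append(".")
        pos3[c] = len(seq)
        seq.append(arm3[c])
        struct.append(")")

    sequence = "".join(seq)
    structure = "".join(struct)
    mature_iv = (pos5[m0], pos5[m0 + mature_len - 1] + 1)
    # Star: partners of the mature columns, shifted by the 2-nt 3' overhang.
    p_lo = pos3[m0 + mature_len - 1]
    p_hi = pos3[m0]
    star_iv: tuple[int, int] | None = (p_lo + 2, p_hi + 3)
    if star_iv[1] > len(sequence):
        star_iv = None
    return Hairpin(sequence, structure, mature_iv, star_iv)


def _isoform_variants(
    hairpin: Hairpin, rng: np.random.Generator, n: int
) -> list[str]:
    """End variants of the mature (<=2 nt total end shift), drawn from the
    precursor context so they still map to the host transcript."""
    a, b = hairpin.mature_interval
    shifts = [
        (d5, d3)
        for d5 in (-2, -1, 0, 1, 2)
        for d3 in (-2, -1, 0, 1, 2)
        if 0 < abs(d5) + abs(d3) <= 2
    ]
    out: list[str] = []
    order = rng.permutation(len(shifts))
    for idx in order:
        d5, d3 = shifts[idx]
        na, nb = a - d5, b + d3
        if na < 0 or nb > len(hairpin.sequence) or nb - na < 18:
            continue
        var = hairpin.sequence[na:nb]
        if var != hairpin.mature and var not in out:
            out.append(var)
        if len(out) == n:
            break
    return out


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as out:
        for header, seq in records:
            out.write(f">{header}\n{seq}\n")


def simulate_libraries(
    config: SimulationConfig, outdir: str | Path
) -> SimulatedDataset:
    """Generate both libraries, all references, and the truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- plant hairpins -------------------------------------------------
    lens = sorted(config.mature_len_dist)
    probs = np.array([config.mature_len_dist[l] for l in lens])
    probs = probs / probs.sum()
    n_conserved = int(round(config.conserved_fraction * config.n_hairpins))
    hairpins: list[Hairpin] = []
    seen_matures: set[str] = set()
    for i in range(config.n_hairpins):
        while True:
            mature_len = int(rng.choice(lens, p=probs))
            stem_len = int(
                rng.integers(
                    max(config.hairpin_stem_len_range[0], mature_len),
                    config.hairpin_stem_len_range[1] + 1,
                )
            )
            loop_len = int(
                rng.integers(config.loop_len_range[0], config.loop_len_range[1] + 1)
            )
            bulges = int(rng.choice([0, 0, 0, 1, 2]))
            hp = build_hairpin(
                stem_len,
                loop_len,
                bulges,
                rng,
                mature_len=mature_len,
                five_prime_u_prob=config.five_prime_u_prob,
                wobble_prob=config.wobble_prob,
            )
            if hp.mature not in seen_matures:
                seen_matures.add(hp.mature)
                break
        hairpins.append(hp)

    # --- transcripts hosting the hairpins -------------------------------
    n_transcripts = max(config.n_transcripts, config.n_hairpins)
    transcripts: dict[str, str] = {}
    records: list[HairpinRecord] = []
    for t in range(n_transcripts):
        tid = f"t{t:04d}"
        tlen = int(
            rng.integers(
                config.transcript_len_range[0], config.transcript_len_range[1] + 1
            )
        )
        seq = _rand_seq(rng, tlen)
        if t < config.n_hairpins:
            hp = hairpins[t]
            offset = int(rng.integers(0, max(1, tlen - len(hp.sequence))))
            seq = seq[:offset] + hp.sequence + seq[offset + len(hp.sequence) :]
            kind = "conserved" if t < n_conserved else "novel"
            mirna_id = f"sim-mir{t:04d}"
            family = f"MIR{100 + t // 2}" if kind == "conserved" else None
            records.append(
                HairpinRecord(
                    mirna_id=mirna_id,
                    kind=kind,
                    precursor=hp.sequence,
                    structure=hp.structure,
                    mature=hp.mature,
                    mature_interval=hp.mature_interval,
                    star=hp.star,
                    star_interval=hp.star_interval,
                    arm=hp.arm,
                    host_transcript=tid,
                    offset=offset,
                    family=family,
                )
            )
        transcripts[tid] = seq

    # --- planted target sites (in hairpin-free transcripts) -------------
    target_sites: list[tuple[str, str, int, int]] = []
    n_targets = int(round(config.target_site_fraction * config.n_hairpins))
    free = [f"t{t:04d}" for t in range(config.n_hairpins, n_transcripts)]
    for j in range(min(n_targets, len(free))):
        rec = records[j]
        tid = free[j]
        site = revcomp(rec.mature)
        seq = transcripts[tid]
        start = int(rng.integers(0, len(seq) - len(site)))
        transcripts[tid] = seq[:start] + site + seq[start + len(site) :]
        target_sites.append((rec.mirna_id, tid, start, start + len(site)))

    # --- references -----------------------------------------------------
    ncrna_classes = ("rRNA", "tRNA", "snRNA", "snoRNA")
    ncrna_records = []
    for i in range(config.n_ncrna_refs):
        cls = ncrna_classes[i % len(ncrna_classes)]
        length = int(rng.integers(80, 151))
        ncrna_records.append((f"ncRNA{i:03d} class={cls}", _rand_seq(rng, length)))

    mature_records = []
    for rec in records:
        if rec.kind == "conserved":
            num = rec.family.replace("MIR", "")
            letter = "ab"[int(rec.mirna_id[-4:]) % 2]
            mature_records.append(
                (f"gbi-miR{num}{letter} {rec.family}", rec.mature)
            )

    # --- per-tag expected counts ---------------------------------------
    abund = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(records))
    abund /= abund.sum()
    true_log2fc: dict[str, float] = {}
    de_flags = rng.random(len(records)) < config.de_fraction
    for i, rec in enumerate(records):
        if config.de_fraction == 0 or not de_flags[i]:
            true_log2fc[rec.mirna_id] = 0.0
        else:
            mag = rng.uniform(*config.de_log2fc_range)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            true_log2fc[rec.mirna_id] = float(sign * mag)

    # Split each fold change symmetrically between the two libraries and
    # renormalize per library, so both libraries hit their nominal depth;
    # the common rescaling shifts every realized fold change by the same
    # constant, which is folded back into the recorded truth.
    drawn = np.array([true_log2fc[r.mirna_id] for r in records])
    raw1 = abund * 2.0 ** (drawn / 2.0)
    raw2 = abund * 2.0 ** (-drawn / 2.0)
    p1 = raw1 / raw1.sum()
    p2 = raw2 / raw2.sum()
    shift = math.log2(raw2.sum() / raw1.sum())  # log2(s1/s2)
    for i, rec in enumerate(records):
        true_log2fc[rec.mirna_id] = float(drawn[i] + shift)

    mirna_share = config.clean_fraction
    depth1, depth2 = config.library_depths
    expected_counts: dict[tuple[str, int], float] = {}
    # tag plan: list of (sequence, category, mirna_id, expected_lib1, expected_lib2)
    tag_plan: list[tuple[str, str, str, float, float]] = []
    for i, rec in enumerate(records):
        e1 = depth1 * mirna_share * p1[i]
        e2 = depth2 * mirna_share * p2[i]
        expected_counts[(rec.mirna_id, 1)] = e1
        expected_counts[(rec.mirna_id, 2)] = e2
        hp = hairpins[i]
        n_iso = int(rng.integers(1, 3))
        variants = (
            _isoform_variants(hp, rng, n_iso) if config.isoform_rate > 0 else []
        )
        iso_share = config.isoform_rate if variants else 0.0
        tag_plan.append(
            (rec.mature, "clean_mirna", rec.mirna_id, e1 * (1 - iso_share), e2 * (1 - iso_share))
        )
        for v in variants:
            tag_plan.append(
                (
                    v,
                    "isoform",
                    rec.mirna_id,
                    e1 * iso_share / len(variants),
                    e2 * iso_share / len(variants),
                )
            )
        if rec.star is not None and config.star_fraction > 0:
            tag_plan.append(
                (
                    rec.star,
                    "star",
                    rec.mirna_id,
                    e1 * config.star_fraction,
                    e2 * config.star_fraction,
                )
            )

    # --- draw counts and write reads -----------------------------------
    adapter = config.adapter_seq
    tag_labels: dict[str, str] = {}
    tag_mirna: dict[str, str] = {}
    actual_counts: dict[tuple[str, int], int] = {}

    fq_paths = (outdir / "lib1.fastq", outdir / "lib2.fastq")
    manifest_path = outdir / "manifest.tsv"
    manifest = open(manifest_path, "w")
    manifest.write("read_id\tsequence\tcategory\tmirna_id\tlibrary\n")

    for lib, (depth, fq_path) in enumerate(zip((depth1, depth2), fq_paths), start=1):
        serial = 0
        fq = open(fq_path, "w")

        def emit(insert: str, read_seq: str, category: str, mirna_id: str, n: int):
            nonlocal serial
            lines_fq = []
            lines_mf = []
            qual = "I" * len(read_seq)
            for _ in range(n):
                serial += 1
                rid = f"r{lib}_{serial:08d}"
                lines_fq.append(f"@{rid}\n{read_seq}\n+\n{qual}\n")
                lines_mf.append(f"{rid}\t{insert}\t{category}\t{mirna_id}\t{lib}\n")
            fq.write("".join(lines_fq))
            manifest.write("".join(lines_mf))

        for seq, category, mirna_id, e1, e2 in tag_plan:
            expected = e1 if lib == 1 else e2
            n = int(rng.poisson(expected))
            tag_labels[seq] = category
            tag_mirna[seq] = mirna_id
            if category == "clean_mirna":
                actual_counts[(mirna_id, lib)] = n
            if n > 0:
                emit(seq, seq + adapter, category, mirna_id, n)

        for key in CONTAMINANT_KEYS:
            frac = config.contaminant_fractions.get(key, 0.0)
            n_cat = int(rng.poisson(depth * frac))
            for _ in range(n_cat):
                if key == "adaptor3_null":
                    insert = _rand_seq(rng, int(rng.integers(20, 31)), "ACG")
                    read = insert  # no adapter at all
                elif key == "insert_null":
                    insert = ""
                    read = adapter
                elif key == "adaptor5_contaminant":
                    insert = config.adapter_5p[: int(rng.integers(10, 15))] + _rand_seq(
                        rng, int(rng.integers(5, 12)), "ACG"
                    )
                    read = insert + adapter
                elif key == "short":
                    insert = _rand_seq(rng, int(rng.integers(10, 18)), "ACG")
                    read = insert + adapter
                elif key == "polyA":
                    length = int(rng.integers(18, 23))
                    n_a = math.ceil(0.95 * length)
                    chars = ["A"] * n_a + list(_rand_seq(rng, length - n_a, "CG"))
                    idx = rng.permutation(length)
                    insert = "".join(chars[k] for k in idx)
                    read = insert + adapter
                else:  # ncRNA_fragment
                    header, ref = ncrna_records[int(rng.integers(0, len(ncrna_records)))]
                    flen = int(rng.integers(18, min(31, len(ref) + 1)))
                    start = int(rng.integers(0, len(ref) - flen + 1))
                    insert = ref[start : start + flen]
                    read = insert + adapter
                if insert and insert not in tag_labels:
                    tag_labels[insert] = key
                    tag_mirna[insert] = "-"
                emit(insert, read, key, "-", 1)
        fq.close()
    manifest.close()

    # --- write references and truth ------------------------------------
    mature_path = outdir / "mature_ref.fasta"
    ncrna_path = outdir / "ncrna_ref.fasta"
    tx_path = outdir / "transcripts.fasta"
    _write_fasta(mature_path, mature_records)
    _write_fasta(ncrna_path, ncrna_records)
    _write_fasta(tx_path, sorted(transcripts.items()))

    truth = GroundTruth(
        hairpins=records,
        tag_labels=tag_labels,
        tag_mirna=tag_mirna,
        true_log2fc=true_log2fc,
        expected_counts=expected_counts,
        actual_counts=actual_counts,
        target_sites=target_sites,
    )
    truth.validate(transcripts)

    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w") as out:
        json.dump(
            {
                "hairpins": [asdict(r) for r in records],
                "true_log2fc": true_log2fc,
                "expected_counts": {
                    f"{k[0]}|{k[1]}": v for k, v in expected_counts.items()
                },
                "actual_counts": {
                    f"{k[0]}|{k[1]}": v for k, v in actual_counts.items()
                },
                "target_sites": target_sites,
            },
            out,
            indent=1,
            sort_keys=True,
        )

    return SimulatedDataset(
        config=config,
        fastq=fq_paths,
        mature_reference=mature_path,
        ncrna_reference=ncrna_path,
        transcripts_fasta=tx_path,
        manifest=manifest_path,
        ground_truth_json=gt_path,
        truth=truth,
        transcripts=transcripts,
    )
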