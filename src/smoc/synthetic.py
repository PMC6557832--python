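"""Ground-truth spidroin-like gene models and simulated sequencing reads.

Spidroin genes share a stereotyped architecture: conserved, non-repetitive
N- and C-terminal domains flank a long array of near-identical repeat units
composed from a small vocabulary of peptide motifs — beta-sheet blocks
(poly-alanine runs and (GA)n), beta-turn motifs (GPGGX, GPGQQ, XQQ),
3_10-helix GGX, the arginine motif GGR, and low-complexity spacers.  The
generator emits such genes with exact coordinate truth, plus short-read and
long-read simulators, so the whole assembly pipeline is testable without any
external data.

Repeat copies descend from a single back-translated template: each copy
inherits the template's codons and then receives independent amino-acid
substitutions (``per_copy_divergence``) and synonymous codon resampling
(``codon_noise``).  This mirrors the duplication origin of real repeat
arrays, where copies are highly similar at the DNA level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io import Annotation, SeqRecord, revcomp, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard genetic code, amino acid -> codons (no stops)
_CODON_TO_AA = {}
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _aa = _AA_ORDER[16 * _i + 4 * _j + _k]
            _CODON_TO_AA[_b1 + _b2 + _b3] = _aa
CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    if _aa != "*":
        CODONS.setdefault(_aa, []).append(_codon)


# ---------------------------------------------------------------------------
# Motif grammar
# ---------------------------------------------------------------------------

#: fixed precedence order shared with the annotator
MOTIF_CLASSES = ("poly_A", "GA_repeat", "GPGQQ", "GPGGX", "GGR", "GGX", "XQQ", "spacer")


@dataclass
class MotifGrammar:
    """Sampling rules for the spidroin repeat-motif vocabulary.

    ``x_residues`` excludes A, G and Q by default so that adjacent motifs in a
    spacer-free unit never merge into a different maximal motif (e.g. GPGGA
    followed by poly-A would otherwise fuse into a longer alanine run).
    """

    weights: dict[str, float] = field(default_factory=lambda: {
        "poly_A": 0.20, "GA_repeat": 0.10, "GPGQQ": 0.15, "GPGGX": 0.20,
        "GGR": 0.05, "GGX": 0.20, "XQQ": 0.10, "spacer": 0.0,
    })
    x_residues: str = "SYLVIT"
    spacer_residues: str = "STGAQ"
    poly_a_range: tuple[int, int] = (4, 10)
    ga_range: tuple[int, int] = (3, 8)
    spacer_range: tuple[int, int] = (10, 20)

    def min_length(self, cls: str) -> int:
        return {
            "poly_A": self.poly_a_range[0],
            "GA_repeat": 2 * self.ga_range[0],
            "GPGQQ": 5, "GPGGX": 5, "GGR": 3, "GGX": 3, "XQQ": 3,
            "spacer": self.spacer_range[0],
        }[cls]

    def sample_motif(self, rng: np.random.Generator,
                     max_len: Optional[int] = None) -> tuple[str, str]:
        """Draw one (class, peptide) pair; only classes fitting max_len."""
        classes = [c for c, w in self.weights.items() if w > 0]
        if max_len is not None:
            classes = [c for c in classes if self.min_length(c) <= max_len]
        if not classes:
            raise ValueError(f"no motif class fits in {max_len} residues")
        w = np.array([self.weights[c] for c in classes], dtype=float)
        cls = classes[rng.choice(len(classes), p=w / w.sum())]
        return cls, self.emit(cls, rng, max_len)

    def emit(self, cls: str, rng: np.random.Generator,
             max_len: Optional[int] = None) -> str:
        def rand_x() -> str:
            return self.x_residues[rng.integers(len(self.x_residues))]

        if cls == "poly_A":
            lo, hi = self.poly_a_range
            if max_len is not None:
                hi = min(hi, max_len)
            return "A" * int(rng.integers(lo, hi + 1))
        if cls == "GA_repeat":
            lo, hi = self.ga_range
            if max_len is not None:
                hi = min(hi, max_len // 2)
            return "GA" * int(rng.integers(lo, hi + 1))
        if cls == "GPGQQ":
            return "GPGQQ"
        if cls == "GPGGX":
            return "GPGG" + rand_x()
        if cls == "GGR":
            return "GGR"
        if cls == "GGX":
            return "GG" + rand_x()
        if cls == "XQQ":
            return rand_x() + "QQ"
        if cls == "spacer":
            lo, hi = self.spacer_range
            if max_len is not None:
                hi = min(hi, max_len)
            n = int(rng.integers(lo, hi + 1))
            idx = rng.integers(len(self.spacer_residues), size=n)
            return "".join(self.spacer_residues[i] for i in idx)
        raise ValueError(f"unknown motif class {cls!r}")


def make_repeat_unit(grammar: MotifGrammar, length: int,
                     rng: np.random.Generator, max_tries: int = 200) -> str:
    """Compose a repeat unit of exactly ``length`` residues from the grammar.

    The final residues are filled by motifs that fit; when no class fits the
    remaining space the last motif is dropped and sampling retried, so the
    unit is always an exact concatenation of valid motif instances.
    """
    min_any = min(grammar.min_length(c) for c, w in grammar.weights.items() if w > 0)
    if length < max(grammar.min_length(c) for c in ("GPGQQ", "GPGGX")):
        raise ValueError(f"unit length {length} shorter than the longest fixed motif")
    for _ in range(max_tries):
        parts: list[str] = []
        prev_cls = ""
        remaining = length
        rejects = 0
        dead = False
        while remaining > 0:
            if remaining < min_any:
                # try to grow a stretchable trailing motif
                if parts and set(parts[-1]) == {"A"} and \
                        len(parts[-1]) + remaining <= grammar.poly_a_range[1]:
                    parts[-1] += "A" * remaining
                    remaining = 0
                    continue
                dead = True
                break
            try:
                cls, pep = grammar.sample_motif(rng, max_len=remaining)
            except ValueError:
                dead = True
                break
            # a poly-A block directly after a GA-repeat would merge with its
            # trailing alanine into one longer run and break the motif tiling
            if cls == "poly_A" and prev_cls == "GA_repeat":
                rejects += 1
                if rejects > 20:        # poly-A may be the only class left
                    dead = True
                    break
                continue
            rejects = 0
            parts.append(pep)
            prev_cls = cls
            remaining -= len(pep)
        if not dead and remaining == 0:
            return "".join(parts)
    raise RuntimeError(f"could not compose a {length}-residue unit from grammar")


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------

@dataclass
class GeneParams:
    gene_id: str = "gene1"
    n_terminal_length: int = 150
    c_terminal_length: int = 100
    unit_length: int = 60
    n_repeats: int = 20
    per_copy_divergence: float = 0.01
    codon_noise: float = 0.01
    identical_codons: bool = False
    linker_length: int = 0        # 0 disables linkers
    linker_every: int = 0         # insert a linker after every m-th unit
    intron_after: tuple[int, ...] = ()   # unit indices (1-based) followed by an intron
    intron_length: int = 300
    seed: int = 0


@dataclass
class SpidroinGeneModel:
    """A synthetic spidroin gene with full coordinate truth."""

    gene_id: str
    n_terminal: str
    c_terminal: str
    repeat_unit_template: str
    repeat_units: list[str]          # realized per-copy protein sequences
    n_repeats: int
    per_copy_divergence: float
    linkers: list[str]
    dna: str                         # genomic sequence (introns included)
    truth: list[Annotation]
    params: GeneParams

    @property
    def protein(self) -> str:
        """Translation of the spliced coding sequence."""
        return translate(self.transcript)

    @property
    def transcript(self) -> str:
        """Exonic DNA joined in order (the mRNA-level sequence)."""
        exons = sorted((a for a in self.truth if a.feature_type == "exon"),
                       key=lambda a: a.start)
        return "".join(self.dna[a.start:a.end] for a in exons)


def _back_translate(protein: str, rng: np.random.Generator) -> list[str]:
    return [CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein]


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def random_protein(length: int, rng: np.random.Generator,
                   alphabet: str = AMINO_ACIDS) -> str:
    idx = rng.integers(len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def make_gene(grammar: MotifGrammar, params: GeneParams) -> SpidroinGeneModel:
    """Build a gene: N-domain, repeat array (with optional linkers/introns), C-domain.

    Deterministic for a fixed ``params.seed``.  Each repeat copy shares the
    template's codons, then diverges by amino-acid substitution at
    ``per_copy_divergence`` and synonymous codon resampling at ``codon_noise``
    (both zero when ``identical_codons`` is set).
    """
    rng = np.random.default_rng(params.seed)
    if params.n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    n_term = "M" + random_protein(params.n_terminal_length - 1, rng)
    c_term = random_protein(params.c_terminal_length, rng)
    unit_template = make_repeat_unit(grammar, params.unit_length, rng)
    template_codons = _back_translate(unit_template, rng)

    divergence = 0.0 if params.identical_codons else params.per_copy_divergence
    codon_noise = 0.0 if params.identical_codons else params.codon_noise

    copies_protein: list[str] = []
    copies_dna: list[str] = []
    for _ in range(params.n_repeats):
        prot = _mutate_protein(unit_template, divergence, rng)
        codons = list(template_codons)
        for i, (old, new) in enumerate(zip(unit_template, prot)):
            if old != new:
                codons[i] = CODONS[new][rng.integers(len(CODONS[new]))]
        noisy = np.flatnonzero(rng.random(len(codons)) < codon_noise)
        for i in noisy:
            aa = prot[i]
            codons[i] = CODONS[aa][rng.integers(len(CODONS[aa]))]
        copies_protein.append(prot)
        copies_dna.append("".join(codons))

    linkers: list[str] = []
    use_linker = params.linker_length > 0 and params.linker_every > 0

    # assemble DNA with truth annotations
    gid = params.gene_id
    pieces: list[str] = []
    anns: list[Annotation] = []
    pos = 0

    def add(seq: str, ftype: str, label: str) -> None:
        nonlocal pos
        if seq:
            anns.append(Annotation(gid, pos, pos + len(seq), ftype, label))
            pieces.append(seq)
            pos += len(seq)

    add("".join(_back_translate(n_term, rng)), "n_terminal_domain", "N")
    for i, cdna in enumerate(copies_dna, start=1):
        add(cdna, "repeat_unit", f"unit_{i}")
        if use_linker and i < params.n_repeats and i % params.linker_every == 0:
            link = random_protein(params.linker_length, rng,
                                  alphabet="STGNQ")
            linkers.append(link)
            add("".join(_back_translate(link, rng)), "linker", f"linker_{i}")
        if i in params.intron_after:
            intron = "GT" + "".join(
                "ACGT"[j] for j in rng.integers(4, size=params.intron_length - 4)
            ) + "AG"
            add(intron, "intron", f"intron_{i}")
    add("".join(_back_translate(c_term, rng)), "c_terminal_domain", "C")

    dna = "".join(pieces)
    # exons: maximal coding spans between introns
    introns = [a for a in anns if a.feature_type == "intron"]
    bounds = [0] + sorted(b for a in introns for b in (a.start, a.end)) + [len(dna)]
    exon_no = 0
    for s, e in zip(bounds[::2], bounds[1::2]):
        if e > s:
            exon_no += 1
            anns.append(Annotation(gid, s, e, "exon", f"exon_{exon_no}"))
    anns.append(Annotation(gid, 0, len(dna), "gene", gid))

    return SpidroinGeneModel(
        gene_id=gid, n_terminal=n_term, c_terminal=c_term,
        repeat_unit_template=unit_template, repeat_units=copies_protein,
        n_repeats=params.n_repeats, per_copy_divergence=params.per_copy_divergence,
        linkers=linkers, dna=dna, truth=anns, params=params,
    )


def masp_like_params(**overrides) -> GeneParams:
    """The default desk-scale preset: 150/100-aa termini, 60-aa unit x 20 copies."""
    p = GeneParams()
    return replace(p, **overrides)


def make_tandem_locus(genes: Sequence[SpidroinGeneModel], spacer_bp: int = 0,
                      flank_bp: int = 0, seed: int = 0,
                      locus_id: str = "locus") -> tuple[SeqRecord, list[Annotation]]:
    """Concatenate genes into one locus with random spacers and flanks."""
    if not genes:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)

    def rand_dna(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(4, size=n))

    parts: list[str] = []
    anns: list[Annotation] = []
    pos = 0
    if flank_bp:
        parts.append(rand_dna(flank_bp))
        pos += flank_bp
    for i, gene in enumerate(genes):
        if i > 0 and spacer_bp:
            parts.append(rand_dna(spacer_bp))
            pos += spacer_bp
        parts.append(gene.dna)
        for a in gene.truth:
            anns.append(Annotation(locus_id, a.start + pos, a.end + pos,
                                   a.feature_type, f"{gene.gene_id}:{a.label}",
                                   a.strand))
        pos += len(gene.dna)
    if flank_bp:
        parts.append(rand_dna(flank_bp))
    return SeqRecord(id=locus_id, sequence="".join(parts)), anns


def make_draft_contigs(model: SpidroinGeneModel, locus: SeqRecord,
                       locus_annotations: Sequence[Annotation],
                       keep_units: int = 1) -> list[SeqRecord]:
    """Emulate a short-read draft assembly of the locus around one gene.

    De Bruijn assemblers resolve the unique terminal domains but collapse or
    break inside the repeat array; the emulation keeps each terminus plus
    ``keep_units`` adjacent repeat copies and drops the interior.
    """
    units = sorted((a for a in locus_annotations
                    if a.feature_type == "repeat_unit"
                    and a.label.startswith(model.gene_id + ":")),
                   key=lambda a: a.start)
    gene = next(a for a in locus_annotations
                if a.feature_type == "gene" and a.label.endswith(model.gene_id))
    if len(units) <= 2 * keep_units:
        return [SeqRecord(id=f"{model.gene_id}_contig", sequence=locus.sequence)]
    left_end = units[keep_units - 1].end
    right_start = units[-keep_units].start
    left = locus.sequence[max(0, gene.start - 200):left_end]
    right = locus.sequence[right_start:min(len(locus.sequence), gene.end + 200)]
    return [
        SeqRecord(id=f"{model.gene_id}_contigN", sequence=left),
        SeqRecord(id=f"{model.gene_id}_contigC", sequence=right),
    ]


def make_homolog_queries(model: SpidroinGeneModel, divergence: float = 0.1,
                         n_residues: int = 170, seed: int = 0,
                         ) -> tuple[SeqRecord, SeqRecord]:
    """Terminal-domain queries from a simulated homologue.

    Seed pickup in practice uses the termini of known spidroins from related
    species or paralogues; this emulates one by mutating the gene's own
    protein at ``divergence`` and cutting the first/last ``n_residues``.
    """
    rng = np.random.default_rng(seed)
    homolog = _mutate_protein(model.protein, divergence, rng)
    head = homolog[:min(n_residues, len(homolog))]
    tail = homolog[max(0, len(homolog) - n_residues):]
    return (SeqRecord(f"{model.gene_id}_homolog_N", head),
            SeqRecord(f"{model.gene_id}_homolog_C", tail))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    read_length: int = 150
    paired: bool = True
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    coverage: float = 50.0
    error_rate_subs: float = 0.0
    long_read_mean: float = 7400.0   # matches a long-read N50 of roughly 7.4 kb
    long_read_sigma: float = 0.4     # lognormal shape
    long_read_min: int = 500
    long_error_subs: float = 0.01
    long_error_ins: float = 0.005
    long_error_del: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.error_rate_subs, self.long_error_subs,
                  self.long_error_ins, self.long_error_del):
            if not 0.0 <= p <= 1.0:
                raise ValueError("error probabilities must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


def _apply_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        alt = "ACGT".replace(out[i], "") if out[i] in "ACGT" else "ACGT"
        out[i] = alt[rng.integers(len(alt))]
    return "".join(out)


def simulate_short_reads(template: SeqRecord, p: ReadSimParams) -> list[SeqRecord]:
    """Uniform-coverage short reads from both strands with i.i.d. substitutions.

    Paired mode emits mates named ``<id>/1`` and ``<id>/2`` consecutively.
    """
    rng = np.random.default_rng(p.seed)
    L = len(template.sequence)
    rl = p.read_length
    if L <= rl:
        raise ValueError("template must be longer than read_length")
    reads: list[SeqRecord] = []
    if p.paired:
        n_pairs = int(round(p.coverage * L / (2 * rl)))
        if n_pairs == 0:
            raise ValueError("requested coverage yields zero read pairs")
        for i in range(n_pairs):
            insert = int(round(rng.normal(p.insert_mean, p.insert_sd)))
            insert = max(rl, min(insert, L))
            start = int(rng.integers(0, L - insert + 1))
            frag = template.sequence[start:start + insert]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            r1 = frag[:rl]
            r2 = revcomp(frag)[:rl]
            reads.append(SeqRecord(f"sr{i}/1", _apply_subs(r1, p.error_rate_subs, rng)))
            reads.append(SeqRecord(f"sr{i}/2", _apply_subs(r2, p.error_rate_subs, rng)))
    else:
        n_reads = int(round(p.coverage * L / rl))
        if n_reads == 0:
            raise ValueError("requested coverage yields zero reads")
        for i in range(n_reads):
            start = int(rng.integers(0, L - rl + 1))
            seq = template.sequence[start:start + rl]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(SeqRecord(f"sr{i}", _apply_subs(seq, p.error_rate_subs, rng)))
    return reads


def _apply_long_errors(seq: str, p: ReadSimParams, rng: np.random.Generator) -> str:
    total = p.long_error_subs + p.long_error_ins + p.long_error_del
    if total <= 0:
        return seq
    out: list[str] = []
    r = rng.random(len(seq))
    for i, base in enumerate(seq):
        x = r[i]
        if x < p.long_error_del:
            continue
        if x < p.long_error_del + p.long_error_ins:
            out.append(base)
            out.append("ACGT"[rng.integers(4)])
            continue
        if x < total:
            alt = "ACGT".replace(base, "") if base in "ACGT" else "ACGT"
            out.append(alt[rng.integers(3 if base in "ACGT" else 4)])
            continue
        out.append(base)
    return "".join(out)


def simulate_long_reads(template: SeqRecord, p: ReadSimParams) -> list[SeqRecord]:
    """Long reads with lognormal lengths (truncated to the template) and
    substitution + indel errors at post-correction rates."""
    rng = np.random.default_rng(p.seed)
    L = len(template.sequence)
    mean = min(p.long_read_mean, float(L))
    n_reads = max(1, int(round(p.coverage * L / mean)))
    mu = np.log(p.long_read_mean) - p.long_read_sigma ** 2 / 2
    reads: list[SeqRecord] = []
    for i in range(n_reads):
        length = int(rng.lognormal(mu, p.long_read_sigma))
        length = max(min(length, L), min(p.long_read_min, L))
        start = int(rng.integers(0, L - length + 1))
        seq = template.sequence[start:start + length]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SeqRecord(f"lr{i}", _apply_long_errors(seq, p, rng)))
    return reads


# ---------------------------------------------------------------------------
# Family panel for clustering
# ---------------------------------------------------------------------------

#: seven recipes shaped after the spidroin orthologue groups: distinct motif
#: emphasis per family (poly-A/GGX, proline-rich, GGR-rich, GA-rich,
#: GPGGX-elastic, and two spacer-dominated compositions).
FAMILY_RECIPES: dict[str, dict[str, float]] = {
    "MaSp1": {"poly_A": 0.35, "GGX": 0.40, "GA_repeat": 0.15, "GPGGX": 0.10},
    "MaSp2": {"poly_A": 0.25, "GPGGX": 0.35, "GPGQQ": 0.25, "XQQ": 0.15},
    "MaSp3": {"GGR": 0.45, "poly_A": 0.20, "GPGGX": 0.15, "GA_repeat": 0.20},
    "MiSp":  {"GA_repeat": 0.45, "GGX": 0.30, "poly_A": 0.25},
    "Flag":  {"GPGGX": 0.60, "XQQ": 0.25, "spacer": 0.15},
    "CySp":  {"spacer": 0.60, "poly_A": 0.20, "GA_repeat": 0.20},
    "AcSp":  {"spacer": 0.50, "XQQ": 0.25, "GGX": 0.25},
}
_FAMILY_SPACERS = {"Flag": "STGQA", "CySp": "STANQ", "AcSp": "SVQNT"}


def make_family_panel(seed: int = 0, n_families: int = 7, members: int = 5,
                      member_divergence: float = 0.03,
                      n_domain_length: int = 100, c_domain_length: int = 80,
                      n_units: int = 3, unit_length: int = 50,
                      ) -> tuple[list[SeqRecord], list[int]]:
    """Desk-scale protein panel: ``n_families`` spidroin families, each with a
    private N/C-domain pair and repeat recipe, and ``members`` mutated members.

    Returns (protein records, true family labels).
    """
    rng = np.random.default_rng(seed)
    names = list(FAMILY_RECIPES)[:n_families]
    records: list[SeqRecord] = []
    labels: list[int] = []
    for fam_idx, name in enumerate(names):
        grammar = MotifGrammar(
            weights={c: FAMILY_RECIPES[name].get(c, 0.0) for c in MOTIF_CLASSES},
            spacer_residues=_FAMILY_SPACERS.get(name, "STGAQ"),
        )
        n_dom = random_protein(n_domain_length, rng)
        c_dom = random_protein(c_domain_length, rng)
        units = [make_repeat_unit(grammar, unit_length, rng) for _ in range(n_units)]
        reference = n_dom + "".join(units) + c_dom
        for m in range(members):
            seq = _mutate_protein(reference, member_divergence, rng)
            records.append(SeqRecord(f"{name}_m{m}", seq))
            labels.append(fam_idx)
    return records, labels
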