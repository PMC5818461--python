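"""Built-in retroelement family templates and the bundled reference set.

The bundled protein-domain exemplars (``data/domain_refs_synthetic.faa``)
are *synthetic* stand-ins for a curated retroelement domain library: random
proteins with realistic residue composition and lengths, frozen at build
time from a fixed seed.  They are a documented, swappable fixture — any
FASTA of exemplar proteins named ``{DOMAIN}__{lineage}`` can replace them.
Likewise the CR-motif profile is a synthetic nucleotide consensus: the
motif is defined in the literature positionally (a targeting signal at the
element 3' terminus) without a published consensus for this clade.

Family templates are derived from a common ancestral element whose coding
region is a reverse translation of the reference proteins.  Each family
lineage accumulates its own substitutions (default 0.343 expected events
per site, chosen so that two family lineages show ~55% pairwise nucleotide
identity under the Jukes-Cantor expectation identity = 1/4 + 3/4 e^(-8D/3)),
after which the functional signals every family must keep are restored:
TG…CA LTR termini, the PBS, the polypurine tract, and the CR motif.
Family "A" carries a chromodomain downstream of the integrase instead of a
CR motif, mirroring the one chromodomain-bearing family among the ten.
"""

from __future__ import annotations

import string
from importlib import resources

import numpy as np

from .simulate import DEFAULT_KAPPA, ElementTemplate, mutate

# residues weighted roughly by database background frequencies
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_P = np.array(
    [8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7, 2.4, 4.1, 4.7, 4.0, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9]
)
_AA_P = _AA_P / _AA_P.sum()

# canonical domain lengths (aa) for the synthetic exemplars
DOMAIN_LENGTHS = {"GAG": 400, "PR": 120, "RT": 270, "RH": 130, "INT": 300, "CHROMO": 55}

# 3' ends of the bundled tRNA set; the PBS of an element is complementary
# to one of these (initiator-Met by default).
TRNA_3PRIME = {
    "tRNA-iMet": "GCTCTGATACCA",
    "tRNA-Lys_synthetic": "CTCCCTTAGCCA",
    "tRNA-Trp_synthetic": "GACCGGTTAGCA",
}
PBS_IMET = "TGGTATCAGAGC"  # reverse complement of the iMet 3' end

PPT = "GGGAGGGAGAGGGGA"  # 15-bp polypurine tract
POLY_A = "AAAAAAAAAA"  # poly-A motif upstream of GAG

# synthetic CR-motif consensus (40 bp), conserved across CR-bearing families
CR_MOTIF = "GTCACGGATTGCCTAAGCGTTACGAGATCCGTTGGACTCA"

CODONS = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_ALT_CODONS = {
    "A": ["GCT", "GCA", "GCC"], "G": ["GGA", "GGT", "GGC"], "L": ["CTT", "CTA", "TTG"],
    "S": ["TCT", "TCA", "AGT"], "R": ["AGA", "CGT", "AGG"], "V": ["GTT", "GTA", "GTC"],
    "T": ["ACT", "ACA", "ACC"], "P": ["CCT", "CCA", "CCC"], "I": ["ATT", "ATA", "ATC"],
}


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA), size=length, p=_AA_P))


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    out = []
    for aa in protein:
        choices = _ALT_CODONS.get(aa)
        out.append(rng.choice(choices) if choices else CODONS[aa])
    return "".join(out)


def synthesize_domain_references(seed: int = 715):
    """The frozen synthetic exemplar set: per domain, one exemplar per
    lineage variant for the Gypsy layout plus an independent Copia set."""
    rng = np.random.default_rng(seed)
    refs = []
    base = {d: random_protein(n, rng) for d, n in DOMAIN_LENGTHS.items()}
    for d in ("GAG", "PR", "RT", "RH", "INT", "CHROMO"):
        refs.append((f"{d}__gypsy_crm1", d, "gypsy", base[d]))
    # a second, diverged gypsy lineage exemplar (30% aa replacement)
    for d in ("GAG", "RT", "INT"):
        p = list(base[d])
        idx = rng.choice(len(p), size=int(0.3 * len(p)), replace=False)
        for i in idx:
            p[i] = rng.choice(list(_AA), p=_AA_P)
        refs.append((f"{d}__gypsy_crm2", d, "gypsy", "".join(p)))
    # independent Copia exemplars (different layout, unrelated sequence)
    for d in ("GAG", "PR", "INT", "RT", "RH"):
        refs.append((f"{d}__copia_syn1", d, "copia", random_protein(DOMAIN_LENGTHS[d], rng)))
    return refs


def reference_fasta_path():
    return resources.files("crckit.data") / "domain_refs_synthetic.faa"


def gypsy_base_proteins():
    refs = {rid: seq for rid, d, sf, seq in synthesize_domain_references() if sf == "gypsy"}
    return {d: refs[f"{d}__gypsy_crm1"] for d in ("GAG", "PR", "RT", "RH", "INT", "CHROMO")}


def _random_ltr(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list("ACGT"), size=length - 4, p=[0.31, 0.19, 0.19, 0.31]))
    return "TG" + body + "CA"


def _assemble_internal(proteins: dict, order, rng, filler_bp: int, with_chromo: bool):
    """Internal region: PBS, poly-A, coding ORF in the given domain order,
    optional chromodomain at the ORF 3' end, filler, CR motif (unless the
    chromodomain is present), PPT.  Returns (sequence, domain_layout)."""
    parts = [PBS_IMET, "".join(rng.choice(list("ACGT"), size=30)), POLY_A]
    pos = sum(len(p) for p in parts)
    layout = []
    orf_domains = list(order) + (["CHROMO"] if with_chromo else [])
    for d in orf_domains:
        nt = reverse_translate(proteins[d], rng)
        layout.append((d, pos, pos + len(nt)))
        parts.append(nt)
        pos += len(nt)
    parts.append("".join(rng.choice(list("ACGT"), size=filler_bp)))
    pos += filler_bp
    if not with_chromo:
        layout.append(("CR_MOTIF", pos, pos + len(CR_MOTIF)))
        parts.append(CR_MOTIF)
        pos += len(CR_MOTIF)
    parts.append("".join(rng.choice(list("ACGT"), size=20)))
    parts.append(PPT)
    parts.append("".join(rng.choice(list("ACGT"), size=5)))
    return "".join(parts), tuple(layout)


def _restore_signals(internal: str, layout, ltr: str, with_chromo: bool) -> tuple[str, str]:
    """Re-paste the conserved functional signals after lineage mutation."""
    s = list(internal)
    s[: len(PBS_IMET)] = PBS_IMET
    ppt_at = len(internal) - 5 - len(PPT)
    s[ppt_at : ppt_at + len(PPT)] = PPT
    if not with_chromo:
        for label, a, b in layout:
            if label == "CR_MOTIF":
                s[a:b] = CR_MOTIF
    l = list(ltr)
    l[0:2] = "TG"
    l[-2:] = "CA"
    return "".join(s), "".join(l)


def default_family_templates(
    n_families: int = 10,
    seed: int = 715,
    family_divergence: float = 0.343,
    kappa: float = DEFAULT_KAPPA,
):
    """The ten default autonomous families (A..H, X, Y for n=10).

    Family A carries the chromodomain; the rest carry the CR motif.  LTR
    lengths are drawn per family from 661-781 bp and filler sizes vary so
    element lengths span roughly 6-8 kb.
    """
    rng = np.random.default_rng(seed)
    proteins = gypsy_base_proteins()
    names = list(string.ascii_uppercase[:8]) + ["X", "Y"] + [f"F{i}" for i in range(10, n_families)]
    names = names[:n_families]
    templates = []
    for i, name in enumerate(names):
        with_chromo = name == "A"
        ltr_len = int(rng.integers(661, 782))
        ancestor_ltr = _random_ltr(ltr_len, rng)
        filler = int(rng.integers(500, 2300))
        internal, layout = _assemble_internal(
            proteins, ("GAG", "PR", "RT", "RH", "INT"), rng, filler, with_chromo
        )
        # family lineage divergence from the shared ancestor
        internal_m = mutate(internal, family_divergence, kappa, rng)
        ltr_m = mutate(ancestor_ltr, family_divergence, kappa, rng)
        internal_m, ltr_m = _restore_signals(internal_m, layout, ltr_m, with_chromo)
        templates.append(
            ElementTemplate(
                name=name,
                ltr_seq=ltr_m,
                internal_seq=internal_m,
                domain_layout=layout,
                targeting_motif="chromodomain" if with_chromo else "CR_motif",
            )
        )
    return templates


def copia_template(seed: int = 99) -> ElementTemplate:
    """A Copia-layout element (…INT before RT…) for superfamily tests."""
    rng = np.random.default_rng(seed)
    refs = {d: seq for rid, d, sf, seq in synthesize_domain_references() if sf == "copia"}
    ltr = _random_ltr(300, rng)
    internal, layout = _assemble_internal(refs, ("GAG", "PR", "INT", "RT", "RH"), rng, 400, False)
    return ElementTemplate(name="copia_syn", ltr_seq=ltr, internal_seq=internal, domain_layout=layout, targeting_motif="none")


def nonautonomous_templates(seed: int = 715):
    """TRIM, LARD and TR-GAG derivative templates (non-coding or GAG-only)."""
    rng = np.random.default_rng(seed + 1)
    proteins = gypsy_base_proteins()
    trim_ltr = _random_ltr(150, rng)
    trim_internal = PBS_IMET + "".join(rng.choice(list("ACGT"), size=550)) + PPT + "AC"
    trim = ElementTemplate("TRIM_syn", trim_ltr, trim_internal, (), "none")
    lard_ltr = _random_ltr(700, rng)
    lard_internal = (
        PBS_IMET
        + "".join(rng.choice(list("ACGT"), size=4600))
        + CR_MOTIF
        + "".join(rng.choice(list("ACGT"), size=20))
        + PPT
        + "AC"
    )
    lard = ElementTemplate("LARD_syn", lard_ltr, lard_internal, (("CR_MOTIF", 4612, 4612 + len(CR_MOTIF)),), "CR_motif")
    gag_nt = reverse_translate(proteins["GAG"], rng)
    trgag_internal = PBS_IMET + POLY_A + gag_nt + "".join(rng.choice(list("ACGT"), size=300)) + PPT + "AC"
    trgag = ElementTemplate(
        "TRGAG_syn",
        _random_ltr(400, rng),
        trgag_internal,
        ((("GAG", len(PBS_IMET) + len(POLY_A), len(PBS_IMET) + len(POLY_A) + len(gag_nt)),)),
        "none",
    )
    return [trim, lard, trgag]
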