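"""Synthetic two-group miRNA/mRNA data with planted, recoverable structure.

The generator emulates the study design the pipeline targets: peripheral
white blood cell profiles from fertile (FH, n = 7) and subfertile (SFH,
n = 7) heifers, with one SFH mRNA sample dropped (7 vs 6). It plants:

* differentially expressed miRNAs (negative-binomial counts with a
  log-normal baseline and uniform |log2FC| in [0.5, 2.0], signed at random);
* miRNA->target suppression: for planted pairs the gene's latent
  log-abundance is baseline - coupling_slope x (standardized miRNA latent)
  + noise, exponentiated into NB means, which yields a negative
  within-group correlation only in the group(s) where the pair is active;
* rewiring: a fraction of planted pairs is active in one group only, so
  the involved genes' neighborhoods differ between groups by construction;
* seed sites: toy UTRs carry one canonical site of a recorded class at a
  recorded position for every planted pair, while non-target UTRs are
  rejection-sampled to contain no 6mer-or-better match to any planted
  miRNA's seed;
* one pathway term over-represented among planted target genes, plus
  uniform decoy terms.

Everything is deterministic given the config seed; sub-streams for counts,
sequences and pathways are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mircornet.containers import CountMatrix
from mircornet.targets import SITE_TYPES, _COMPLEMENT, scan_seed_sites

_RNA = np.array(list("ACGU"))


@dataclass
class SyntheticConfig:
    n_fh_mirna: int = 7
    n_sfh_mirna: int = 7
    n_fh_mrna: int = 7
    n_sfh_mrna: int = 6
    n_mirna: int = 341
    n_gene: int = 741
    frac_de_mirna: float = 16 / 341
    de_log2fc_range: tuple = (0.5, 2.0)
    nb_dispersion: float = 0.1
    #: natural-log mean and sd of the log-normal baseline means
    mean_log_mu: tuple = (5.0, 1.5)
    coupling_slope: float = 2.0
    rewired_fraction: float = 0.25
    n_target_pairs: int = 40
    n_regulators: int = 12
    #: sample-to-sample latent log-scale variation of regulator miRNAs
    latent_sd: float = 0.8
    #: residual noise of the planted gene-on-miRNA regression (log scale)
    coupling_noise_sd: float = 0.2
    #: sd of log-normal library-size factors
    lib_sigma: float = 0.2
    #: all-zero miRNA rows planted ahead of the zero filter
    n_zero_mirna: int = 20
    #: low-abundance miRNA rows meant to fall to the CPM prevalence filter
    n_low_mirna: int = 273
    low_log_mu: tuple = (-2.5, 1.0)
    utr_len_range: tuple = (500, 2000)
    #: extend planted sites with a 3'-supplementary complement (miRNA nts
    #: 9..L) so planted duplexes carry real binding affinity
    supplementary_sites: bool = True
    rejection_cap: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_fh_mirna",
            "n_sfh_mirna",
            "n_fh_mrna",
            "n_sfh_mrna",
            "n_mirna",
            "n_gene",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.frac_de_mirna <= 1:
            raise ValueError("frac_de_mirna must be a fraction")
        if self.de_log2fc_range[0] < 0.5:
            raise ValueError(
                "de_log2fc_range lower bound must be >= 0.5 so planted "
                "effects clear the DE fold-change threshold"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class SyntheticTruth:
    de_mirnas: list = field(default_factory=list)  # (mirna_id, sign, log2fc)
    target_pairs: list = field(default_factory=list)  # (mirna, gene, groups)
    rewired_nodes: list = field(default_factory=list)
    planted_sites: list = field(default_factory=list)  # (mir, tx, type, pos)
    enriched_term: str | None = None
    enriched_overlap: int = 0
    gene_ids: list = field(default_factory=list)
    mirna_ids: list = field(default_factory=list)
    n_zero_mirna: int = 0
    n_low_mirna: int = 0
    seed: int = 0

    @property
    def regulators(self) -> list:
        return sorted({m for m, _, _ in self.target_pairs})

    def pairs_active_in(self, group: str) -> list:
        return [(m, g) for m, g, groups in self.target_pairs if group in groups]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float):
    """NB(mean, dispersion alpha) via the gamma-Poisson mixture."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mean * alpha)
    return rng.poisson(lam)


def generate_counts(
    config: SyntheticConfig,
) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Two-group miRNA and mRNA count matrices with planted truth."""
    config.validate()
    if config.coupling_slope <= 0:
        raise ValueError(
            "coupling_slope must be positive to produce negative correlation"
        )
    rng = _rng(config.seed, 0)

    mir_samples = [f"FH{i+1}" for i in range(config.n_fh_mirna)] + [
        f"SFH{i+1}" for i in range(config.n_sfh_mirna)
    ]
    gene_samples = [f"FH{i+1}" for i in range(config.n_fh_mrna)] + [
        f"SFH{i+1}" for i in range(config.n_sfh_mrna)
    ]
    groups = pd.Series(
        {s: ("SFH" if s.startswith("SFH") else "FH") for s in set(mir_samples) | set(gene_samples)}
    )

    n_mir_total = config.n_mirna + config.n_low_mirna + config.n_zero_mirna
    mirna_ids = [f"miR-{i+1:03d}" for i in range(n_mir_total)]
    gene_ids = [f"gene-{i+1:04d}" for i in range(config.n_gene)]

    special = rng.choice(
        n_mir_total,
        size=config.n_zero_mirna + config.n_low_mirna,
        replace=False,
    )
    zero_set = set(special[: config.n_zero_mirna].tolist())
    low_idx = special[config.n_zero_mirna :]
    live_idx = [
        i for i in range(n_mir_total) if i not in zero_set and i not in set(low_idx)
    ]

    # --- differential miRNAs --------------------------------------------
    n_de = int(round(config.frac_de_mirna * config.n_mirna))
    de_idx = rng.choice(live_idx, size=n_de, replace=False) if n_de else np.array([], int)
    lfc = np.zeros(n_mir_total)
    lo, hi = config.de_log2fc_range
    mid = (lo + hi) / 2.0
    n_reg = min(config.n_regulators, n_de)
    reg_idx = de_idx[:n_reg]
    # regulators take effect sizes from the upper half of the range so the
    # planted network structure sits on reliably detectable DEMIs
    for k, i in enumerate(de_idx):
        mag = rng.uniform(mid, hi) if k < n_reg else rng.uniform(lo, hi)
        lfc[i] = mag * rng.choice([-1.0, 1.0])

    # --- baselines and library sizes ------------------------------------
    mu_log_mir = rng.normal(config.mean_log_mu[0], config.mean_log_mu[1], n_mir_total)
    mu_log_mir[low_idx] = rng.normal(
        config.low_log_mu[0], config.low_log_mu[1], len(low_idx)
    )
    mu_log_gene = rng.normal(config.mean_log_mu[0], config.mean_log_mu[1], config.n_gene)
    # planted features get a comfortable baseline: count noise must not
    # drown the latent coupling
    mu_log_mir[reg_idx] = rng.normal(6.5, 0.3, n_reg)

    # planted pairs need a regulator; without DE miRNAs nothing is planted
    n_pairs = min(config.n_target_pairs, config.n_gene) if n_reg else 0
    pair_genes = rng.choice(config.n_gene, size=n_pairs, replace=False)
    mu_log_gene[pair_genes] = rng.normal(6.5, 0.3, n_pairs)

    lib_mir = np.exp(rng.normal(0.0, config.lib_sigma, len(mir_samples)))
    lib_gene = np.exp(rng.normal(0.0, config.lib_sigma, len(gene_samples)))

    # --- miRNA latent abundances ----------------------------------------
    is_sfh_mir = np.array([s.startswith("SFH") for s in mir_samples])
    latent_mir = np.tile(mu_log_mir[:, None], (1, len(mir_samples)))
    latent_mir += np.log(2.0) * np.outer(lfc, is_sfh_mir)
    reg_noise = rng.normal(0.0, config.latent_sd, (n_reg, len(mir_samples)))
    latent_mir[reg_idx] += reg_noise

    # --- planted pairs and their activity pattern -----------------------
    n_rewired = int(round(config.rewired_fraction * n_pairs))
    active: list[tuple] = []
    for k in range(n_pairs):
        if k < n_rewired:
            active.append(("FH",) if k % 2 == 0 else ("SFH",))
        else:
            active.append(("FH", "SFH"))
    pair_regulator = [reg_idx[k % n_reg] for k in range(n_pairs)] if n_reg else []

    # --- gene latent abundances -----------------------------------------
    latent_gene = np.tile(mu_log_gene[:, None], (1, len(gene_samples)))
    sample_pos = {s: i for i, s in enumerate(mir_samples)}
    group_cols = {
        "FH": [i for i, s in enumerate(gene_samples) if not s.startswith("SFH")],
        "SFH": [i for i, s in enumerate(gene_samples) if s.startswith("SFH")],
    }
    for grp in ("FH", "SFH"):
        if not group_cols[grp]:
            raise ValueError(f"zero samples in group {grp}")

    for k in range(n_pairs):
        g = pair_genes[k]
        m = pair_regulator[k]
        for grp, cols in group_cols.items():
            noise = rng.normal(0.0, config.coupling_noise_sd, len(cols))
            if grp in active[k]:
                x = np.array(
                    [latent_mir[m, sample_pos[gene_samples[c]]] for c in cols]
                )
                z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros_like(x)
                latent_gene[g, cols] = mu_log_gene[g] - config.coupling_slope * z + noise
            else:
                latent_gene[g, cols] = mu_log_gene[g] + noise

    # --- draw counts -----------------------------------------------------
    mean_mir = np.exp(latent_mir) * lib_mir
    mean_gene = np.exp(latent_gene) * lib_gene
    counts_mir = _nb_draw(rng, mean_mir, config.nb_dispersion)
    counts_gene = _nb_draw(rng, mean_gene, config.nb_dispersion)
    counts_mir[sorted(zero_set), :] = 0
    # bookkeeping for the zero filter: planted zero rows plus low-abundance
    # rows that happened to draw all zeros
    n_zero_observed = int((counts_mir.sum(axis=1) == 0).sum())

    truth = SyntheticTruth(
        de_mirnas=[
            (mirna_ids[i], "up" if lfc[i] > 0 else "down", float(lfc[i]))
            for i in sorted(de_idx.tolist())
        ],
        target_pairs=[
            (mirna_ids[pair_regulator[k]], gene_ids[pair_genes[k]], active[k])
            for k in range(n_pairs)
        ],
        rewired_nodes=sorted(
            gene_ids[pair_genes[k]] for k in range(n_pairs) if len(active[k]) == 1
        ),
        gene_ids=gene_ids,
        mirna_ids=mirna_ids,
        n_zero_mirna=n_zero_observed,
        n_low_mirna=config.n_low_mirna,
        seed=config.seed,
    )
    mir_cm = CountMatrix(
        pd.DataFrame(counts_mir, index=mirna_ids, columns=mir_samples),
        groups,
        "miRNA",
    )
    gene_cm = CountMatrix(
        pd.DataFrame(counts_gene, index=gene_ids, columns=gene_samples),
        groups,
        "gene",
    )
    return mir_cm, gene_cm, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_RNA[rng.integers(0, 4, length)])


def _not_nt(rng: np.random.Generator, forbidden: str) -> str:
    choices = [c for c in "ACGU" if c != forbidden]
    return choices[rng.integers(0, len(choices))]


def _decoy_utr(
    rng: np.random.Generator,
    length: int,
    seeds_rc: dict[str, str],
    cap: int,
    tx: str,
    chunk: int = 64,
) -> str:
    """Rejection-sample a UTR with no 6mer-or-better match to any seed.

    Sampling is chunkwise (each chunk redrawn until the chunk plus the
    preceding overlap is clean), which keeps rejection sampling tractable
    when many seeds must be avoided at once; a full final scan re-asserts
    the guarantee.
    """
    parts: list[str] = []
    tail = ""
    remaining = length
    while remaining > 0:
        size = min(chunk, remaining)
        for _ in range(cap):
            cand = _random_seq(rng, size)
            window = tail + cand
            if not any(rc in window for rc in seeds_rc.values()):
                break
        else:
            offender = next(m for m, rc in seeds_rc.items() if rc in window)
            raise RuntimeError(
                f"rejection sampling cap reached for {tx}: seed of "
                f"{offender} keeps matching"
            )
        parts.append(cand)
        tail = (tail + cand)[-5:]
        remaining -= size
    seq = "".join(parts)
    assert not any(rc in seq for rc in seeds_rc.values())
    return seq


def _site_sequence(mir: str, site_type: str) -> str:
    """UTR-side (5'->3') sequence of a canonical site for this miRNA."""
    seed_rc = "".join(_COMPLEMENT[c] for c in reversed(mir[1:7]))
    m8 = _COMPLEMENT[mir[7]]
    if site_type == "8mer":
        return m8 + seed_rc + "A"
    if site_type == "7mer-m8":
        return m8 + seed_rc
    if site_type == "7mer-A1":
        return seed_rc + "A"
    return seed_rc


def generate_sequences(
    truth: SyntheticTruth, config: SyntheticConfig
) -> tuple[dict, dict]:
    """Random miRNA and UTR sequences with planted canonical seed sites.

    Returns ``(mirna_seqs, utr_seqs)`` keyed by miRNA id / transcript id
    (one transcript per gene, ``<gene>.t1``). Planted sites are recorded in
    ``truth.planted_sites`` as (mirna_id, transcript_id, site_type,
    1-based position). Non-target UTRs are rejection-sampled to carry no
    6mer-or-better match to any planted miRNA's seed.
    """
    if not truth.mirna_ids:
        raise ValueError("truth is not populated; run generate_counts first")
    rng = _rng(truth.seed, 1)
    mirna_seqs = {
        mid: _random_seq(rng, int(rng.integers(21, 23))) for mid in truth.mirna_ids
    }
    regulators = truth.regulators
    seeds_rc = {
        m: "".join(_COMPLEMENT[c] for c in reversed(mirna_seqs[m][1:7]))
        for m in regulators
    }

    pairs_by_gene: dict[str, list] = {}
    for m, g, _ in truth.target_pairs:
        pairs_by_gene.setdefault(g, []).append(m)

    lo, hi = config.utr_len_range
    utr_seqs: dict[str, str] = {}
    truth.planted_sites = []
    site_cycle = 0
    for gene in truth.gene_ids:
        tx = f"{gene}.t1"
        length = int(rng.integers(lo, hi + 1))
        if gene not in pairs_by_gene:
            utr_seqs[tx] = _decoy_utr(rng, length, seeds_rc, config.rejection_cap, tx)
            continue

        seq = list(_random_seq(rng, length))
        used: list[tuple[int, int]] = []
        for m in pairs_by_gene[gene]:
            mir = mirna_seqs[m]
            site_type = SITE_TYPES[site_cycle % len(SITE_TYPES)]
            site_cycle += 1
            site = _site_sequence(mir, site_type)
            m8 = _COMPLEMENT[mir[7]]
            # assemble the full planted block 5'->3' on the UTR:
            # [3'-supplementary complement][m8-forbidding flank?][site][A1-forbidding flank?]
            # The supplementary block pairs miRNA nucleotides 9..L so the
            # planted duplex has high affinity, not just a seed match.
            sup = (
                "".join(_COMPLEMENT[c] for c in reversed(mir[8:]))
                if config.supplementary_sites
                else ""
            )
            pre = _not_nt(rng, m8) if site_type in ("6mer", "7mer-A1") else ""
            post = _not_nt(rng, "A") if site_type in ("6mer", "7mer-m8") else ""
            block = sup + pre + site + post
            site_off = len(sup) + len(pre)  # site start within the block
            for _ in range(config.rejection_cap):
                start = int(rng.integers(10, length - len(block) - 10))
                if all(start + len(block) <= a or start >= b for a, b in used):
                    break
            else:
                raise RuntimeError(f"could not place a site for {m} in {tx}")
            used.append((start, start + len(block)))
            seq[start : start + len(block)] = list(block)
            truth.planted_sites.append((m, tx, site_type, start + site_off + 1))
        utr_seqs[tx] = "".join(seq)

    # construction check: every planted site is recoverable by the scanner
    for m, tx, site_type, pos in truth.planted_sites:
        hits = scan_seed_sites(mirna_seqs[m], utr_seqs[tx], m, tx)
        if not any(h.site_type == site_type and h.utr_start == pos for h in hits):
            raise RuntimeError(f"planted site not recoverable: {m} {tx} {site_type}")
    return mirna_seqs, utr_seqs


def generate_targetscan_table(
    truth: SyntheticTruth, mirna_seqs: dict, utr_seqs: dict
) -> pd.DataFrame:
    """TargetScan-like prediction table for the truly DE miRNAs.

    Seed-site hits of each truly differential miRNA over all UTRs become
    rows with a synthetic cumulative weighted context++ score: planted
    pairs draw from [-1.2, -0.45] (always past the -0.4 confidence cut),
    incidental hits from [-0.8, 0.1] (mixed). Column names match the
    pipeline defaults (miRNA, gene, context_score).
    """
    rng = _rng(truth.seed, 3)
    planted = {(m, g) for m, g, _ in truth.target_pairs}
    de_ids = [m for m, _, _ in truth.de_mirnas]
    rows = []
    for m in de_ids:
        hit_genes = set()
        for tx, utr in utr_seqs.items():
            gene = tx.rsplit(".", 1)[0]
            if scan_seed_sites(mirna_seqs[m], utr, m, tx):
                hit_genes.add(gene)
        hit_genes |= {g for mm, g in planted if mm == m}
        for gene in sorted(hit_genes):
            if (m, gene) in planted:
                score = rng.uniform(-1.2, -0.45)
            else:
                score = rng.uniform(-0.8, 0.1)
            rows.append((m, gene, round(float(score), 4)))
    return pd.DataFrame(rows, columns=["miRNA", "gene", "context_score"])


def generate_pathways(
    truth: SyntheticTruth,
    n_decoys: int = 24,
    enriched_size: int = 15,
    enriched_overlap: int = 10,
    decoy_size_range: tuple = (10, 60),
) -> dict[str, set]:
    """GMT-style term -> gene-set dict with one planted enriched term.

    The enriched term contains ``enriched_overlap`` planted target genes
    (recorded in the truth) topped up with random non-target genes;
    decoy terms are drawn uniformly from the gene universe.
    """
    if not truth.gene_ids:
        raise ValueError("truth is not populated; run generate_counts first")
    rng = _rng(truth.seed, 2)
    universe = list(truth.gene_ids)
    if decoy_size_range[1] > len(universe) or enriched_size > len(universe):
        raise ValueError("gene universe smaller than the largest term")

    terms: dict[str, set] = {}
    target_genes = sorted({g for _, g, _ in truth.target_pairs})
    if target_genes:
        overlap = min(enriched_overlap, len(target_genes))
        members = set(
            rng.choice(target_genes, size=overlap, replace=False).tolist()
        )
        others = [g for g in universe if g not in set(target_genes)]
        members |= set(
            rng.choice(others, size=enriched_size - overlap, replace=False).tolist()
        )
        terms["PLANTED_TERM"] = members
        truth.enriched_term = "PLANTED_TERM"
        truth.enriched_overlap = overlap
    else:
        truth.enriched_term = None
        truth.enriched_overlap = 0
    for k in range(n_decoys):
        size = int(rng.integers(decoy_size_range[0], decoy_size_range[1] + 1))
        terms[f"DECOY_{k+1:02d}"] = set(
            rng.choice(universe, size=size, replace=False).tolist()
        )
    return terms
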