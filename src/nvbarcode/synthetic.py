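"""Synthetic hierarchically structured barcode datasets.

Emulates a multi-rank barcode collection (class > order > family > genus >
species, several specimens per species) by simulating ancestral sequences
down the taxonomy: each class gets an independent random root; each child
taxon's ancestor is its parent's ancestor with random substitutions at the
rank's rate; each specimen is its species ancestor mutated at the
within-species rate. Substitutions are uniform to a different base
(Jukes-Cantor-like) — only the positional geometry of the resulting vectors
matters downstream, not a realistic evolutionary model. Specimen counts per
species are drawn from a range, giving the uneven species sizes real barcode
collections show. A fixed seed makes the output byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sequences import SequenceRecord, TaxonomyLabel, seq_stats

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

Range = tuple[int, int]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; all ranges are inclusive.

    Default rates place within-species divergence (0.5%) well below
    between-species divergence (5%), with deeper ranks progressively more
    diverged. Root length range matches a standardized short barcode
    fragment (500-800 bp).
    """

    n_classes: int = 3
    orders_per_class: Range = (2, 2)
    families_per_order: Range = (1, 1)
    genera_per_family: Range = (2, 2)
    species_per_genus: Range = (2, 3)
    specimens_per_species: Range = (5, 20)
    length_range: Range = (500, 800)
    rate_order: float = 0.12
    rate_family: float = 0.09
    rate_genus: float = 0.07
    rate_species: float = 0.05
    rate_specimen: float = 0.005
    indel_rate: float = 0.0
    mean_indel_length: float = 3.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    #: optional deterministic species-count cycle over genera (overrides
    #: species_per_genus sampling); (2, 3) over 12 genera gives exactly 30 species
    species_pattern: tuple[int, ...] | None = (2, 3)
    seed: int = 0

    def validate(self) -> None:
        rates = (self.rate_order, self.rate_family, self.rate_genus,
                 self.rate_species, self.rate_specimen)
        if not all(0 <= r < 1 for r in rates):
            raise ValueError("substitution rates must lie in [0, 1)")
        if self.rate_specimen > self.rate_species:
            raise ValueError("within-species rate must not exceed between-species rate")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        for name in ("orders_per_class", "families_per_order", "genera_per_family",
                     "species_per_genus", "specimens_per_species", "length_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    if rate == 0.0:
        return seq.copy()
    out = seq.copy()
    hit = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _indels(seq: np.ndarray, rate: float, mean_len: float,
            rng: np.random.Generator, comp) -> np.ndarray:
    if rate == 0.0:
        return seq
    parts = []
    i = 0
    arr = seq
    while i < arr.size:
        if rng.random() < rate:
            L = 1 + rng.geometric(1.0 / mean_len)
            if rng.random() < 0.5:  # deletion
                i += L
                continue
            parts.append(_BASES[rng.choice(4, size=L, p=comp)])
        parts.append(arr[i:i + 1])
        i += 1
    if not parts:
        return arr[:1].copy()
    return np.concatenate(parts)


def _rand_int(rng: np.random.Generator, r: Range) -> int:
    return int(rng.integers(r[0], r[1] + 1))


def generate_dataset(spec: SyntheticSpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate labeled barcode records plus a truth table.

    Returns (records, truth) where truth is a per-record TSV-ready table with
    the five-rank taxonomy, generating rates, and an ``outlier`` flag column
    (all False; see :func:`spike_outliers`).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition, dtype=float)
    comp = comp / comp.sum()
    records: list[SequenceRecord] = []
    rows: list[dict] = []
    sp_counter = 0
    genus_counter = 0
    for ci in range(spec.n_classes):
        length = _rand_int(rng, spec.length_range)
        class_anc = _BASES[rng.choice(4, size=length, p=comp)]
        cname = f"Class{ci + 1}"
        for oi in range(_rand_int(rng, spec.orders_per_class)):
            order_anc = _mutate(class_anc, spec.rate_order, rng)
            oname = f"{cname}_Order{oi + 1}"
            for fi in range(_rand_int(rng, spec.families_per_order)):
                fam_anc = _mutate(order_anc, spec.rate_family, rng)
                fname = f"{oname}_Fam{fi + 1}"
                for gi in range(_rand_int(rng, spec.genera_per_family)):
                    gen_anc = _mutate(fam_anc, spec.rate_genus, rng)
                    gname = f"{fname}_Gen{gi + 1}"
                    if spec.species_pattern:
                        n_species = spec.species_pattern[
                            genus_counter % len(spec.species_pattern)]
                    else:
                        n_species = _rand_int(rng, spec.species_per_genus)
                    genus_counter += 1
                    for si in range(n_species):
                        sp_anc = _mutate(gen_anc, spec.rate_species, rng)
                        sp_counter += 1
                        sname = f"Species{sp_counter:03d}"
                        tax = TaxonomyLabel(class_=cname, order=oname,
                                            family=fname, genus=gname, species=sname)
                        for mi in range(_rand_int(rng, spec.specimens_per_species)):
                            s = _mutate(sp_anc, spec.rate_specimen, rng)
                            s = _indels(s, spec.indel_rate, spec.mean_indel_length,
                                        rng, comp)
                            rid = f"{sname}_{mi + 1:02d}"
                            records.append(SequenceRecord(
                                rid, s.tobytes().decode("ascii"), tax))
                            rows.append({
                                "id": rid, "class": cname, "order": oname,
                                "family": fname, "genus": gname, "species": sname,
                                "rate_species": spec.rate_species,
                                "rate_specimen": spec.rate_specimen,
                                "outlier": False,
                            })
    truth = pd.DataFrame(rows)
    return records, truth


def spike_outliers(records: list[SequenceRecord], truth: pd.DataFrame,
                   n: int = 2, length_delta: int = 120, gc_delta: float = 0.05,
                   species: str | None = None, seed: int = 0
                   ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Make ``n`` specimens of one species longer and more GC-rich.

    Emulates divergent within-species barcodes (longer, higher GC) that fail
    to cluster with their conspecifics. The inserted segment's composition is
    chosen so the whole-sequence GC fraction rises by about ``gc_delta``.
    Flags are recorded in the truth table's ``outlier`` column.
    """
    if n == 0:
        return records, truth
    if length_delta < 1:
        raise ValueError("length_delta must be >= 1 when n > 0")
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        sp = r.taxonomy.species if r.taxonomy else ""
        by_species.setdefault(sp, []).append(i)
    if species is None:
        species = max(by_species, key=lambda s: len(by_species[s]))
    idxs = by_species.get(species, [])
    if n > len(idxs):
        raise ValueError(f"species {species!r} has only {len(idxs)} specimens")
    chosen = list(idxs[:n])
    out = list(records)
    truth = truth.copy()
    for i in chosen:
        r = out[i]
        L = len(r.seq)
        g = sum(1 for c in r.seq if c in "GC")
        # inserted segment carries x G's so overall GC rises by about gc_delta
        x = int(round((L + length_delta) * (g / L + gc_delta) - g))
        x = max(0, min(length_delta, x))
        seg = ["G" if j < x else "A" for j in range(length_delta)]
        rng.shuffle(seg)
        pos = int(rng.integers(0, L + 1))
        new_seq = r.seq[:pos] + "".join(seg) + r.seq[pos:]
        out[i] = replace(r, seq=new_seq)
        truth.loc[truth["id"] == r.id, "outlier"] = True
        st = seq_stats(out[i])
        assert st.length == L + length_delta
    return out, truth


def benchmark_spec(seed: int = 0) -> SyntheticSpec:
    """The default benchmark: 30 species (3x2x1x2x{2,3}), 5-20 specimens each,
    0.5% within-species and 5% between-species divergence."""
    return SyntheticSpec(seed=seed)
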