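# anicode

**Hierarchical genome codes from fragment-based average nucleotide
identity (ANI).**

`anicode` assigns every genome-sequenced organism a compact, permanent,
hierarchical code derived purely from genome similarity — no taxonomic
judgement required. It is aimed at microbiologists, virologists and
epidemiologists who need to name and relate newly sequenced isolates
(bacterial chromosomes, mitochondrial genomes, viral genomes) at
resolutions ranging from family-level down to near-identical outbreak
strains, where Linnaean names stop and ad-hoc strain labels begin.

## The idea

A code is a vector of non-negative integers over 24 positions
`A…X`, each tied to an ANI threshold:

| position  | A  | B  | C  | D  | E  | F  | G  | H  | I    | … | M    | … | V     | W      | X       |
|-----------|----|----|----|----|----|----|----|----|------|---|------|---|-------|--------|---------|
| ANI %     | 60 | 70 | 80 | 85 | 90 | 95 | 98 | 99 | 99.5 | … | 99.9 | … | 99.99 | 99.999 | 99.9999 |

Genomes are registered sequentially. The first genome gets `0` at every
position. Each new genome *q* is compared against all registered
genomes using fragment-based ANI (ANIb-style):

1. *q* is cut into consecutive 1020 bp fragments (per contig);
2. each fragment is locally aligned to the subject genome; fragments
   aligning over ≥ 70% of their length with ≥ 30% identity pass;
3. `ANI = mean identity of passed fragments`, and the *percentage of
   aligned fragments* = passed / total.

Among subjects with ≥ 20% aligned fragments, the highest-ANI genome is
the anchor. The code walk copies the anchor's value at every position
whose threshold the ANI strictly exceeds; at the first failed position
a fresh number is issued (scoped to the sibling group sharing the same
code prefix) and all later positions are 0. A genome to which nothing
aligns (< 20% aligned fragments) founds a new lineage at position A.
Consequently **the further right two codes agree, the more similar the
two organisms** — codes approximate phylogeny without ever being
revised.

An optional second filtration step keeps only fragments whose identity
lies within ± 0.1 percentage points of the median, approximating the
vertically inherited core genome and suppressing the distortion caused
by horizontally transferred regions.

## Worked example

```python
from anicode import CladeSpec, balanced_clade_newick, build_registry, simulate_clade

# simulate 4 genomes: two pairs (~99.6% ANI within, ~92% between)
spec = CladeSpec(root_length=20_000,
                 newick=balanced_clade_newick([(2, 0.04), (2, 0.002)]),
                 seed=1)
genomes, ledger = simulate_clade(spec)
registry = build_registry(genomes)
print(registry.provenance_table()[["genome_id", "code", "assigned_from", "ani_pct"]])
```

prints (codes abbreviated to the first ten positions here):

```
  genome_id                                     code assigned_from    ani_pct
0      g1.1  0_A_0_B_0_C_0_D_0_E_0_F_0_G_0_H_0_I_0_J…                     NaN
1      g1.2  0_A_0_B_0_C_0_D_0_E_0_F_0_G_0_H_0_I_1_J…          g1.1  99.570367
2      g2.1  0_A_0_B_0_C_0_D_0_E_1_F_0_G_0_H_0_I_0_J…          g1.2  91.735954
3      g2.2  0_A_0_B_0_C_0_D_0_E_1_F_0_G_0_H_0_I_1_J…          g2.1  99.594877
```

Read it as: `g1.2` shares positions A–I with `g1.1` (ANI 99.57 clears
every threshold up to 99.5 but not 99.6, so a fresh `1` appears at J);
`g2.1` is ~92% identical to the first pair, clearing thresholds up to
90 but not 95, hence the fresh `1` at F that marks the second
species-level lineage; `g2.2` then nests inside it. Grouping genomes by
any code prefix recovers the simulated clades.

The same workflows are available from the shell:

```bash
anicode simulate --newick "(a:0.01,b:0.01);" --root-length 20000 --seed 1 --out clade/
anicode assign --registry registry.jsonl --init clade/a.fasta clade/b.fasta
anicode ani clade/a.fasta clade/b.fasta          # all-against-all ANI table
anicode permute --n-orders 100 --seed 1 --out report/ clade/*.fasta
anicode export --registry registry.jsonl --positions V,W,X
```

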