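# matdrive

Exact genetics of CRISPR homing gene drives with **dominant maternal
effects**: cross enumeration, multi-generation drive dynamics, and
estimation of editing rates from progeny counts.

## The problem

A CRISPR homing drive (mutagenic chain reaction) carries Cas9 and a gRNA
targeting its own insertion site. In the germline of a heterozygote the
wild-type allele is cut and, with probability *x*, repaired by HDR using
the drive chromosome — converting the heterozygote toward homozygosity.
With probability 1 − *x* the break is repaired by NHEJ, destroying the
target site and creating a drive-**resistant** allele *R*.

A second, non-Mendelian channel creates resistance: a drive-carrying
mother deposits Cas9 protein and gRNA into her eggs. This maternal load
mutates wild-type alleles of the **zygote** — whatever the zygote's own
genotype — with probability *y*, producing resistant alleles written *R\**
(genetically identical to *R*; the star records how the mutation arose).
Because germline precursor cells (pole cells) inherit this maternal
cytoplasm, the mutations are heritable. The practical consequence for
drive deployments: resistance can appear, including **homozygous
resistance in a single generation**, even in offspring whose genomes carry
no editing components at all.

`matdrive` is for modellers and experimentalists who need to quantify this
channel: it enumerates any single cross exactly (rational arithmetic, no
sampling), propagates genotype frequencies through pedigrees and
populations (deterministic and Wright–Fisher), estimates the underlying
rates from progeny-class counts with Wilson score intervals, and generates
matched synthetic datasets for power and recovery studies.

## The model

For a cross (mother × father) with parameters *x*, *y* ∈ [0, 1]:

1. **Germline homing** — in each drive-carrying parent, every germline
   WT allele becomes GD with probability *x*, else R (NHEJ). Resistant
   alleles are immune (target site gone).
2. **Mendelian segregation** — each germline allele is transmitted with
   probability ½; R\* is transmitted as R.
3. **Zygotic maternal effect** — iff the mother carries ≥ 1 GD allele,
   each WT allele of the zygote independently becomes R\* with
   probability *y*.

The offspring genotype distribution is the exact composition of the three
operators. The canonical worked example is a two-generation pedigree:
G0 = GD/WT male × WT female, all G1 progeny (sex 1:1) backcrossed to wild
type, so that G1 **females** carrying the drive expose the maternal
effect in G2. At *x* = 0.95, *y* = 0.87:

| G2 class | maternal effect on | off |
|---|---|---|
| heterozygous resistant R/+ | 2.6271875 % → **2.6 %** | 3.6875 % → **3.7 %** |
| homozygous resistant R/R\* | 1.0603125 % → **1.06 %** | **0** |

The toggle difference 3.6875 − 2.6271875 = 1.0603125 is exactly the
R/R\* mass: the maternal effect upgrades heterozygous resistants into
single-generation homozygous resistants (½ · 0.975 · 0.025 · 0.87).

## Worked example

```sh
$ matdrive --quiet cross --mother GD/WT --father WT/WT --x 0.95 --y 0.87
genotype        probability     percentage
GD/R*   0.84825 84.825
GD/WT   0.12675 12.675
R/R*    0.02175 2.175
R/WT    0.00325 0.325
```

A drive mother transmits the drive to 97.5 % of offspring
((1 + x)/2), and her maternal Cas9/gRNA load then converts 87 % of the
paternal WT alleles to R\* — so 2.175 % of her offspring are already
homozygous-resistant (R/R\*), in one generation.

```sh
$ matdrive --quiet g2          # the two-generation pedigree, x=0.95 y=0.87
genotype        probability     percentage
GD/WT   0.537103125     53.7103125
GD/R*   0.413521875     41.3521875
R/WT    0.026271875     2.6271875
WT/WT   0.0125  1.25
R/R*    0.010603125     1.0603125
het_resistant(R/+)      0.026271875     2.6271875
hom_resistant(R/R)      0.010603125     1.0603125
```

Library use mirrors the CLI:

```python
from matdrive import DriveParams, g2_backcross, round_percent
g2 = g2_backcross(DriveParams(0.95, 0.87))
round_percent(g2.p_label("R/R*"), 2)   # 1.06
```

Other subcommands: `drive` (deterministic or Wright–Fisher trajectories
under random mating or wild-type backcrossing), `fit` (per-cross
disruption rate *d* and HDR fraction *h* with 95 % Wilson intervals from a
`cross_id,GAL4plus,dGAL4,QF2plus` CSV), `simulate germline|brains|cohort`
(seeded synthetic datasets), and `reproduce` (below).

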