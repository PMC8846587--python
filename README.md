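# dcl3dice

Mechanistic simulation of how the plant Dicer **DCL3** converts short
Pol IV–RDR2 double-stranded RNAs into the 23/24-nt siRNA duplexes that
guide RNA-directed DNA methylation (RdDM) in *Arabidopsis*.

In RdDM, RNA polymerase IV transcribes short first strands (~25–40 nt)
from silenced loci; RDR2 copies each into a second strand, initiating
1–2 nt internal to the Pol IV transcript's 3′ end (Δ) and often adding
one untemplated 3′ nucleotide. The resulting duplex carries a 1–2 nt 3′
overhang at each end, and these end features form a *dicing code* that
determines which end DCL3 engages and whether 23- or 24-nt siRNAs
result. `dcl3dice` implements that code as an explicit rule engine so
that substrate→product outcomes, strand provenance and pool composition
can be computed, enumerated and simulated.

## The model

For a duplex end with 3′ overhang *o* ≥ 0, DCL3 anchors the recessed 5′
terminus of the *measured* strand M and makes up to two cuts:

* RNase III **domain B** cuts M after position `L = measure_len + δ`
  (default 24; δ is a −1/0/+1 register jitter applied only to blunt
  ends), provided `L < len(M)`.
* RNase III **domain A** cuts the complementary strand C so that its
  product has length `p = L − cut_offset + o` (default offset 2),
  provided `0 < p < len(C)`.

Hence a 37/38-mer with *o* = 1 yields a 24 + 23 nt duplex; with *o* = 2,
24 + 24. Each new product end carries a 2-nt 3′ overhang of the measured
strand. When no internal cut exists at either end (e.g. a 24/23-mer with
1- and 2-nt overhangs — exactly the geometry of a product), the duplex
is *refractory* and returned intact; duplexes shorter than the ruler on
both strands are degraded to a ladder of ≥17-nt pieces. End choice is
scored as

```
score(end) = w_overhang(o) × w_nt(5′ nucleotide) × w_chem(5′ chemistry)
```

with A = U > C = G, monophosphate ≥ triphosphate ≫ hydroxyl, and
1–2 nt overhang > blunt (only the orderings are constrained by data;
the weights are configurable).

## Worked example

```python
from dcl3dice import DicingParams, dice, get_fixture

oc = dice(get_fixture("fig1C_37_38"), DicingParams())
print(len(oc.product.top), len(oc.product.bottom),
      [len(f) for f in oc.fragments])
```

prints `24 23 [13, 15]`: the 37-nt strand is measured and cut to a 24-mer
retaining its 5′ terminus, the 38-nt strand is cut offset by 2 nt into a
23-mer retaining its 3′ terminus, and the distal 13/15-nt pieces are
released. Running `python examples/simulate_pool.py` dices a 5,000-duplex
simulated Pol IV–RDR2 ensemble and prints

```
24-mers: 6007   23-mers: 3993
24:23 ratio = 1.50
scenario counts: {'S1': 2904, 'S2': 1050, 'S3': 1046, 'OTHER': 0}
```

— 24-mers outnumber 23-mers because two dicing routes produce a 24-mer
from each strand (left-end dicing guided by the RDR2 tail; right-end
dicing with Δ = 2) while only one route produces a 23-mer from each
strand. `python examples/dicing_routes.py` prints that route table.

## Command line

```sh
dcl3dice fixtures --out fx/                  # bench substrate panel (TSV + FASTA)
dcl3dice dice --substrates fx/substrates.tsv --seed 1 --out products.tsv
dcl3dice simulate --n 1000 --seed 1 --out sim/   # ensemble -> products + summary
dcl3dice routes --out routes.tsv
dcl3dice summarize --products sim/products.tsv --out summary.tsv
```

Engine and generator parameters can be overridden with a YAML config
(`--config`, blocks `engine:` and `generator:`; unknown keys are
rejected).

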