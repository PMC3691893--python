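# pabaflux

¹³C NMR isotopomer analysis of urinary *N*-acetyl-PABA — a noninvasive
"chemical biopsy" of hepatic cytosolic acetyl-CoA.

## The problem

Cytosolic acetyl-CoA is the precursor pool for hepatic *de novo*
lipogenesis, but it cannot be observed in vivo by NMR and is unstable in
extracts. When *p*-amino benzoic acid (PABA) is supplied in drinking water,
the liver N-acetylates it from exactly this pool and excretes
*N*-acetyl-PABA in urine. The ¹³C multiplet pattern of the acetyl group
therefore reports the isotopomer composition of lipogenic acetyl-CoA: in
mice drinking [U-¹³C]fructose and [1-¹³C]glucose, the acetyl carbon 1
(carboxyl) and carbon 2 (methyl) resonances each show a singlet (singly
labeled acetyl) flanked by a doublet (J₁₂ = 51.0 Hz, the [1,2-¹³C₂]
species), while two aromatic PABA carbons at natural abundance
(1.11% ¹³C) act as the internal enrichment standard.

The package is for tracer-metabolism researchers who want to quantify
those spectra, attribute acetyl-CoA production to its dietary precursors,
and understand how pyruvate cycling limits that attribution.

## The model

With per-carbon aromatic reference area *P*, correction factor CF from a
nonenriched standard, and multiplet areas C1S, C1D, C2S, C2D:

```
total C2 enrichment (%)        = (C2S + C2D)/P × CF × 1.11
total [2-¹³C], [1,2-¹³C₂] (%)  = C2S/C2, C2D/C2 fractions of total C2
excess [2-¹³C] (%)             = total [2-¹³C] − 1.11
total C1 enrichment (%)        = total [1,2-¹³C₂] × C1/C1D
excess [1-¹³C] (%)             = (C1S/C1) × total C1 − 1.11
```

Substrate attribution, with eᵢ the excess enrichments and half of each
sugar's triose units labeled (tracer fractions of 0.5):

```
fructose (%)        = e₁₂ / 0.5                       (cycling-proof)
glucose upper (%)   = (e₂ + e₁) / 0.5
glucose lower (%)   = (e₂ − e₁) / 0.5
glucose at f (%)    = (e₂ + (2f−1)·e₁) / 0.5
endogenous (%)      = 100 − fructose − glucose
```

The [1-¹³C]acetyl species exists only because pyruvate cycling
(pyruvate carboxylase → oxaloacetate ↔ fumarate → PEPCK/malic enzyme →
pyruvate) scrambles the glucose label through the symmetric fumarate pool.
The bundled atom-mapping simulator (`pabaflux.cycling`) propagates
positional isotopomers through PDH, citrate-synthase turns and the cycling
loop, verifies that the fructose estimate is exact regardless of cycling,
that the glucose truth always lies inside the bounds, and that under a
fed-state liver flux scenario roughly half of the [1-¹³C]acetyl stems from
directly cycled [3-¹³C]pyruvate — the regime in which the midpoint
estimate (f = 0.5) is appropriate.

## Worked example

Simulate a four-animal study at known ground truth (excesses
0.4 / 1.1 / 2.0%), then analyze it end to end:

```bash
$ pabaflux simulate --out demo --excess 0.4 1.1 2.0 --n-animals 4 --seed 11
wrote 4 spectra + reference to demo

$ pabaflux report demo/animal_0*.csv --reference demo/reference_nonenriched.csv
Acetyl-CoA isotopomer study report
correction factor CF = 1.0988

 animal  excess_1_13c  excess_2_13c  excess_12_13c2
      1          0.41          1.22            2.23
      2          0.35          1.00            1.98
      3          0.33          0.91            2.10
      4          0.52          0.98            1.84

                       quantity units  value
           excess [1-13C]acetyl     %   0.40
           excess [2-13C]acetyl     %   1.03
        excess [1,2-13C2]acetyl     %   2.04
                glucose (upper)     %   2.86
                glucose (lower)     %   1.25
                glucose (f=0.5)     %   2.06
                       fructose     %   4.07
endogenous (with glucose upper)     %  93.06
endogenous (with glucose lower)     %  94.68
```

Each animal's spectrum is integrated against its multiplet windows, the
correction factor is derived from the nonenriched reference (here 1.0988,
absorbing the synthetic T₁/nOe attenuation), and the cohort-mean excesses
are converted to contributions: fructose supplies ~4% of acetyl-CoA,
glucose 1.3–2.9% depending on the cycling assumption, and endogenous
(unlabeled) substrates the remaining >93%.

The simulator-based self-check:

```bash
$ pabaflux validate
simulated excesses: [1-13C]=0.275% [2-13C]=0.733% [1,2-13C2]=1.456%
fructose: estimate 2.941% vs truth 2.941%
glucose: truth 1.471% in [0.926, 2.036] -> OK
[1-13C]acetyl from direct cycling: 49.1%
```

The same functionality is available as a library; see
`pabaflux.run_pipeline`, `pabaflux.quantify_profile`,
`pabaflux.estimate_all` and `pabaflux.steady_state`.

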