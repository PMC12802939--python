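# telog4

Analysis pipeline for ribonucleotide-substituted telomeric G-quadruplexes:
CD-based conformation calling and melting-temperature extraction, smFRET
folding-dynamics analysis, and RNase H2 cleavage quantification by
ribonucleotide position class — together with a synthetic-data module so
every stage can be exercised, tested and benchmarked without instrument
data.

## The scientific problem

The G-rich strand of human telomeres, (TTAGGG)ₙ, folds into G-quadruplexes
(G4s). Telomerase misincorporates ribonucleotides (rNMPs) into this DNA, and
a single embedded rNMP can change which G4 topology forms, how stable it is,
and whether the ribonucleotide-excision-repair nuclease RNase H2 can reach
and cleave it. The constructs studied are the 24-mer (TTAGGG)₄ with one
ribose substitution, written in lowercase-r notation (`TTAGGGTTArGGG…` = rG
at position 10). Each substitution position maps to a structural class by
its offset within the repeat: the two thymines (T), the loop adenine (A),
and the first/second/third tetrad guanine (G1/G2/G3).

The package implements the complete computational workflow around four
measurements:

* **CD conformation calling** — G4 topologies have characteristic circular
  dichroism extrema (parallel: max ~265 / min ~240 nm; antiparallel chair:
  max ~290 / min ~265; antiparallel basket: maxima ~250, ~290 / minima
  ~235, ~265; 3+1 hybrid: maxima ~265, ~290 / minima ~240, ~275). Spectra
  are scored by extrema matching, with a non-negative least-squares band
  decomposition to resolve mixed populations.
* **Melting temperature** — a third-order polynomial is fitted to the
  single-wavelength ellipticity-vs-temperature ramp and Tm is the root of
  its second derivative: for *aT³ + bT² + cT + d*, `Tm = −b/(3a)`.
* **smFRET dynamics** — per-frame efficiency `E = I_A / (I_A + I_D)`; pooled
  short-movie histograms fitted with a single Gaussian; 3-minute traces
  classified as static-folded (E ≥ 0.6 throughout), unfolded (E < 0.6
  throughout) or dynamic, with a dwell filter absorbing sub-0.5 s noise
  excursions.
* **RNase H2 cleavage** — percent cleavage = cleaved / (cleaved + uncleaved)
  band intensity, aggregated over replicates, grouped by rNMP position
  class, and compared between K⁺ and Na⁺ conditions.

## Worked example

```python
from telog4 import (parse_sequence, classify_position, classify_conformation,
                    fit_cubic_tm, delta_tm, SyntheticConfig,
                    gen_cd_spectrum, gen_melting_curve, gen_fret_traces,
                    classify_trace, compute_fret)
from collections import Counter

seq = parse_sequence("TTAGGGTTArGGGTTAGGGTTAGGG", name="TEL-R10")
site = classify_position(seq)
print(f"{seq.name}: rNMP at position {site.position} "
      f"(repeat {site.repeat_index}, class {site.position_class.value})")

cfg = SyntheticConfig(seed=1)
spectrum = gen_cd_spectrum({"antiparallel_basket": 1.0}, cfg)
call = classify_conformation(spectrum)
print(f"CD call: {sorted(call.called)} (mixture: {call.mixture_flag})")

tel = fit_cubic_tm(gen_melting_curve(58.86, cfg, model="cubic"))
var = fit_cubic_tm(gen_melting_curve(46.99, cfg, model="cubic"))
print(f"Tm(TEL) = {tel.tm:.2f} C, Tm(variant) = {var.tm:.2f} C, "
      f"dTm = {delta_tm(var, tel):+.2f} C")

traces, truth = gen_fret_traces(200, cfg)
pred = Counter(classify_trace(compute_fret(t)).label for t in traces)
print("trace types:", {k: f"{100*v/200:.1f}%" for k, v in sorted(pred.items())})
```

prints

```
TEL-R10: rNMP at position 10 (repeat 2, class G1)
CD call: ['antiparallel_basket'] (mixture: False)
Tm(TEL) = 58.86 C, Tm(variant) = 46.99 C, dTm = -11.87 C
trace types: {'dynamic': '21.0%', 'static_folded': '72.0%', 'unfolded': '7.0%'}
```

The rG at position 10 is a first-tetrad guanine (G1) in the second repeat —
the class whose substitution switches the canonical 3+1 hybrid fold to an
antiparallel basket and drops Tm by ~12 °C. The simulated trace-type
percentages recover the generator's canonical-construct fractions
(74.3 / 17.8 / 7.9) to within binomial sampling error.

There is also a CLI mirroring the library stages:

```bash
telog4 simulate --seed 1 --out run/
telog4 cd-classify run/cd_spectrum.csv --out run/conf/
telog4 cd-melt run/melting_curve.csv --auto-window --out run/melt/
telog4 fret-classify run/fret_traces.tsv --labels run/fret_labels.tsv --out run/cls/
telog4 cleave-summarize run/cleavage.tsv --out run/cleave/
```

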