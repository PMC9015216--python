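# morphdispersal

Natal-dispersal analysis for color-polymorphic populations breeding in
nest-box networks.

## The problem

In long-term nest-box studies of cavity-nesting raptors (the motivating
system is the tawny owl, *Strix aluco*, at its cold northern range margin),
natal dispersal is the straight-line distance from the box an owl fledged
from to the box of its first breeding attempt. Two questions recur:

1. **Is observed dispersal genuinely short, or just censored?** A finite
   study area cannot detect settlers beyond its edge. The package answers
   this with a randomization test: for each recruit, the distances to every
   box *available in its hatch year* (networks grow — boxes added after an
   enlargement year are invisible to earlier cohorts) form its candidate
   set; drawing one candidate per recruit and taking the median, repeated
   *m* = 999 times, gives the null distribution of medians under completely
   random settlement. The randomized P value is
   (#{null medians ≤ observed median} + 1) / (m + 1),
   so the smallest attainable P is 1/1000.

2. **Do environmental conditions move heritable phenotypes differently?**
   Plumage color (gray vs reddish-brown, one locus, two alleles, brown
   dominant) is a proxy for genotype. Dispersal distance *d* of recruit
   *i* is modelled as a linear mixed model

   d_i = β₀ + β₁·brown_i + β₂·anomaly_i + β₃·(brown_i × anomaly_i)
         + β₄·prey_i + β₅·male_i + β₆·mass_i (+ age terms)
         + u_year + u_brood + u_box + ε_i

   with crossed random intercepts for hatch year, brood and natal box,
   REML estimation, and marginal (Type III) F tests whose denominator
   degrees of freedom use Satterthwaite's approximation. The interaction
   β₃ is the quantity of interest: a nonzero value means cold winters
   (negative anomaly = winter mean below the 1981–2010 baseline) push the
   two morphs' dispersal in opposite directions. A weighted binomial GLM of
   yearly brown proportion on the anomaly checks whether winter conditions
   shift morph composition at all.

Because field data of this kind are rarely public, the package includes a
first-class synthetic-population generator whose generating process is
exactly the fitted model (Mendelian inheritance, mixed-model dispersal
kernel, nearest-box settlement), so the whole pipeline is testable and its
statistical properties (calibration, power, parameter recovery) are
verifiable.

## Worked example

```bash
python examples/04_morph_environment_models.py
```

prints (seed 7, study-scale synthetic population, generating interaction
2.37 km/°C):

```
brown-proportion GLM: slope +0.027 +/- 0.069 per C, z = 0.39, P = 0.70 (40 cohorts)

all-ages LMM (n=179):
  anomaly x morph(brown): +2.16 +/- 0.43 km/C, F(1,160.1) = 24.73, P = 0.000

one-year-olds LMM (n=77):
  anomaly x morph(brown): +2.21 +/- 0.63 km/C, F(1,31.4) = 12.28, P = 0.001

predicted dispersal (km) at anomaly -3 / 0 / +3 C:
  gray :  12.3   10.6    9.0
  brown:   6.1   10.9   15.7
```

Reading: winter temperature does not change *which* morphs recruit (GLM
P = 0.70) but changes *where* they settle — the positive interaction means
brown recruits shorten dispersal after cold winters while gray recruits
lengthen it, and the marginal-effect lines cross. The other examples cover
the generator (`01`), covariate construction (`02`), the randomization
null (`03`, observed median ~10.6 km vs ~15.0 km expected under random
settlement, P = 0.001) and the full CSV-to-report pipeline (`05`).

A thin CLI wraps the same calls for shell use:

```bash
morphdispersal simulate --seed 7 --out data/
morphdispersal all --config config.yaml --seed 7 --out results/
```

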