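# Synthetic stand-in for the human vernier-offset thresholds of the cited
# behavioural studies (originals appear only in figures).  Values are
# *relative* threshold triplets (vernier alone, 1 flanker, many flankers)
# in arbitrary arcsec-like units; only their ordering and rough ratios
# matter (they anchor psychometric fits and the Fourier band search).
# Most categories show the human U-shape (uncrowding); edit freely.
circles: [50, 230, 110]
Gestalts: [50, 240, 110]
hexagons: [50, 220, 120]
irregular1: [50, 230, 150]
irregular2: [50, 230, 120]
lines: [40, 200, 90]
octagons: [50, 220, 130]
patternIrregular: [50, 210, 140]
patternStars: [50, 200, 100]
squares: [50, 250, 100]
stars: [50, 240, 140]
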