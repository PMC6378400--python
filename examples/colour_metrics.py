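"""Colour metrics of a red wing marking against a dark background.

Builds cone catches for a typical red marking and its background, then prints
every metric a predator-vision analysis uses: luminance (double-cone catch),
tetrahedral saturation, opponency hue, and the chromatic/achromatic contrasts
in just-noticeable differences (JND).  Contrasts above 1 JND mean an avian
viewer should be able to tell the two patches apart.
"""

from aposignal import (
    BLUETIT_VS,
    ConeCatch,
    achromatic_contrast,
    chromatic_contrast,
    discriminable,
    hue,
    luminance,
    metrics_from_catches,
    saturation,
)

# red marking: LW catch elevated; dark background: flat and dim
marking = ConeCatch(uv=0.05, sw=0.04, mw=0.04, lw=0.28, dbl=0.16)
background = ConeCatch(uv=0.075, sw=0.075, mw=0.075, lw=0.075, dbl=0.075)

print(f"marking luminance    : {luminance(marking):.3f}  (double-cone catch)")
print(f"marking saturation   : {saturation(marking):.3f}  (0 = achromatic, 0.75 = spectral vertex)")
print(f"marking hue          : {hue(marking):.3f}  ((LW+UV)/(SW+MW); >1 = redder / more UV)")

ds = chromatic_contrast(marking, background, BLUETIT_VS)
dl = achromatic_contrast(marking, background, BLUETIT_VS)
print(f"chromatic contrast   : {ds:.2f} JND  (receptor-noise model, blue tit cone ratios)")
print(f"achromatic contrast  : {dl:.2f} JND  (|ln dbl ratio| / Weber fraction)")
print(f"discriminable        : {discriminable(ds)}  (strictly > 1 JND)")

m = metrics_from_catches(marking, background, BLUETIT_VS, relative_marking_area=25.0)
print("\nfull metric vector   :", {k: round(v, 3) for k, v in m.as_dict().items()})
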