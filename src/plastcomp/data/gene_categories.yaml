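# Default functional categories for standard plastome protein-coding genes.
# Override with a user-supplied YAML of the same shape (category -> [genes]).
photosynthetic apparatus:
  [psaA, psaB, psaC, psaI, psaJ,
   psbA, psbB, psbC, psbD, psbE, psbF, psbH, psbI, psbJ, psbK, psbL, psbM,
   psbN, psbT, psbZ,
   petA, petB, petD, petG, petL, petN,
   ycf3, ycf4]
photosynthetic metabolism:
  [atpA, atpB, atpE, atpF, atpH, atpI,
   ndhA, ndhB, ndhC, ndhD, ndhE, ndhF, ndhG, ndhH, ndhI, ndhJ, ndhK,
   rbcL]
gene expression:
  [rpl2, rpl14, rpl16, rpl20, rpl22, rpl23, rpl32, rpl33, rpl36,
   rps2, rps3, rps4, rps7, rps8, rps11, rps12, rps14, rps15, rps16, rps18, rps19,
   rpoA, rpoB, rpoC1, rpoC2, infA]
other:
  [ycf1, ycf2, ycf15, ccsA, cemA, matK, accD, clpP]
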