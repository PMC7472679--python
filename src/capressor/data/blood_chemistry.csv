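# Blood-chemistry panels (arterial pH, ionized calcium) by cohort, animal and
# experimental round, hand-transcribed from the source publication's printed
# tables. Rounds an animal did not survive to have no row; the literal value
# "missing" marks a round that happened but whose blood-gas data were lost.
# suspect=1 marks cells whose printed values are ambiguous or physiologically
# implausible (see the note column); they are transcribed verbatim, never
# corrected. bolus_ca_count / epi_count (cohort 3 only) are the number of
# calcium / epinephrine doses given in that round.
cohort,animal,round,pH,iCa,bolus_ca_count,epi_count,suspect,note
1,1,baseline,7.46,1.29,,,0,
1,1,1,7.29,1.21,,,0,
1,1,2,7.32,1.12,,,0,
1,1,3,7.31,1.10,,,0,
1,1,4,7.28,1.17,,,0,
1,1,5,7.29,1.20,,,0,
1,2,baseline,7.50,1.26,,,0,
1,2,1,7.27,1.21,,,0,
1,2,2,7.23,1.24,,,0,
1,2,3,7.37,1.23,,,0,
1,2,4,7.34,1.28,,,0,
1,2,5,7.35,1.26,,,0,
1,3,baseline,7.47,1.28,,,0,
1,3,1,7.32,1.24,,,0,
1,3,2,7.32,1.25,,,0,
1,3,3,7.29,1.24,,,0,
1,3,4,7.32,1.27,,,0,
1,3,5,7.40,1.25,,,0,
1,4,baseline,7.49,1.29,,,0,
1,4,1,7.25,1.20,,,0,
1,4,2,7.20,1.25,,,0,
1,4,3,7.24,1.18,,,0,
1,4,4,7.29,1.15,,,0,
1,4,5,7.24,1.17,,,0,
1,5,baseline,7.50,1.35,,,0,
1,5,1,7.53,1.33,,,0,
1,5,2,7.48,1.26,,,0,
1,5,3,7.51,1.26,,,0,
1,5,4,7.49,1.25,,,0,
1,5,5,7.31,1.25,,,0,
1,6,baseline,7.49,1.36,,,0,
1,6,1,7.46,1.25,,,0,
1,6,2,7.46,1.22,,,0,
1,6,3,7.39,1.25,,,0,
1,6,4,7.36,1.28,,,0,
1,6,5,7.42,1.72,,,1,implausible iCa; transcribed verbatim
1,7,baseline,7.48,1.39,,,0,
1,7,1,7.51,1.34,,,0,
1,7,2,7.48,1.33,,,0,
1,7,3,7.51,1.30,,,0,
1,7,4,7.50,1.28,,,0,
1,7,5,7.50,1.28,,,0,
1,8,baseline,7.51,1.41,,,0,
1,8,1,7.33,1.29,,,0,
1,9,baseline,7.50,1.40,,,0,
1,9,1,7.40,1.07,,,0,
1,9,2,7.44,1.27,,,0,
1,9,3,7.45,1.28,,,0,
1,9,4,7.38,1.28,,,0,
1,10,baseline,7.47,1.36,,,0,
1,10,1,7.09,1.28,,,0,
1,11,baseline,7.48,1.33,,,0,
1,11,1,7.24,1.32,,,0,
1,11,2,7.27,1.25,,,0,
1,12,baseline,7.50,1.17,,,0,
1,12,1,7.33,1.27,,,0,
1,12,2,7.33,1.27,,,0,
1,13,baseline,7.48,1.29,,,0,
1,13,1,7.33,1.25,,,0,
1,13,2,7.38,1.22,,,0,
1,14,baseline,7.48,1.30,,,0,
1,14,1,7.33,1.32,,,0,
2,1,baseline,7.24,1.19,,,1,single printed record; baseline placement inferred from group sizes
2,2,baseline,7.23,1.20,,,0,
2,3,baseline,7.49,1.23,,,0,
2,3,1,7.32,1.14,,,0,
2,4,baseline,7.48,1.29,,,0,
2,4,1,7.48,1.29,,,0,
2,5,baseline,7.51,1.13,,,0,
2,6,baseline,7.43,1.17,,,0,
2,7,baseline,7.45,1.33,,,0,
2,7,1,7.25,1.21,,,0,
2,7,2,7.33,1.11,,,0,
2,7,3,7.31,1.16,,,0,
2,8,baseline,7.42,1.07,,,0,
2,8,1,7.23,1.07,,,0,
2,8,2,7.28,0.92,,,0,
2,8,3,7.28,0.88,,,0,
2,9,baseline,7.48,1.34,,,0,
2,9,1,7.34,1.17,,,0,
2,9,2,7.33,1.11,,,0,
2,9,3,7.32,1.11,,,0,
2,9,4,7.34,1.08,,,0,
2,10,baseline,7.45,1.23,,,0,
2,10,1,7.32,1.11,,,0,
2,10,2,7.20,0.92,,,0,
2,10,3,7.20,1.06,,,0,
3,1,baseline,missing,missing,,,0,
3,1,1,missing,missing,0,1,0,
3,1,2,missing,missing,0,0,0,
3,2,baseline,7.49,1.08,,,0,
3,2,1,7.16,1.21,0,1,1,ambiguous print; could read iCa 1.2 / 1 bolus / 0 epi
3,2,2,7.50,0.94,0,0,0,
3,2,3,7.37,0.92,0,0,0,
3,2,4,7.22,1.05,0,0,0,
3,3,baseline,7.45,1.38,,,0,
3,3,1,7.47,1.38,0,6,0,
3,3,2,7.04,1.37,,,1,bolus/epi counts not printed
3,4,baseline,7.62,1.25,,,0,
3,4,1,7.42,1.39,0,0,0,
3,4,2,7.16,1.29,1,0,0,
3,4,3,7.39,1.12,0,1,0,
3,4,4,7.30,1.17,0,1,0,
3,5,baseline,7.44,1.34,,,0,
3,5,1,7.01,1.26,1,0,0,
3,5,2,7.28,1.42,1,0,0,
3,5,3,7.40,1.25,1,0,0,
3,5,4,7.21,1.22,0,0,0,
3,6,baseline,7.47,1.44,,,0,
3,6,1,7.20,1.25,0,0,0,
3,6,2,7.32,1.29,1,0,0,
3,6,3,7.24,1.49,2,0,0,
3,6,4,missing,missing,0,0,0,
3,7,baseline,7.45,1.38,,,0,
3,7,1,7.03,missing,0,5,1,ambiguous print; iCa not resolvable
3,8,baseline,7.47,1.40,,,0,
3,8,1,7.44,1.30,3,0,0,
3,8,2,7.40,1.24,3,0,0,
3,8,3,7.34,1.36,2,0,0,
3,8,4,missing,missing,1,2,0,
3,9,baseline,7.46,1.25,,,0,
3,9,1,7.47,1.33,1,1,0,
3,9,2,7.28,1.22,5,0,0,
3,9,3,7.40,1.30,5,0,0,
3,9,4,7.30,1.72,0,1,1,implausible iCa; transcribed verbatim
3,10,baseline,7.49,1.39,,,0,
3,10,1,7.01,0.87,2,0,0,
3,10,2,7.30,1.48,1,1,0,
3,10,3,7.29,1.40,3,0,0,
3,10,4,7.39,1.37,0,0,0,
3,11,baseline,7.44,1.39,,,0,
3,11,1,7.29,1.32,0,0,0,
3,11,2,7.29,1.27,3,3,0,
3,11,3,missing,missing,1,3,0,
3,11,4,missing,missing,0,0,0,
3,12,baseline,7.44,1.33,,,0,
3,12,1,7.29,1.23,1,0,0,
3,12,2,missing,missing,0,0,0,
3,13,baseline,7.43,1.47,,,0,
3,13,1,7.26,1.23,0,0,0,
3,13,2,7.14,1.27,3,2,0,
3,13,3,missing,missing,0,0,0,
3,14,baseline,7.45,1.36,,,0,
3,14,1,7.35,1.24,0,0,0,
3,14,2,7.48,1.18,0,0,0,
3,14,3,7.47,1.11,0,0,0,
3,14,4,missing,missing,0,0,0,
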