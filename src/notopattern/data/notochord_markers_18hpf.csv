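gene,expression,enrichment,score
emilin3a,5055.75,1118.16,5653.16
ntd5,5929.62,134.03,794.74
col2a1a,9083.50,67.75,633.59
cmn,1536.94,330.67,508.22
loxl5b,1264.29,330.84,418.28
col9a1b,1511.20,226.72,342.62
ta,1443.23,162.65,234.74
LOC100333762,642.86,303.86,195.34
lgals1l1,2163.88,86.59,187.38
col9a2,1331.86,103.37,137.68
si:ch211-125-g7.4,501.98,272.60,136.84
si:dkey-12l12.1,408.15,304.23,127.17
col9a3,754.32,140.39,105.90
LOC100334188,393.62,205.68,80.96
pmp22b,1001.80,68.64,68.76
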