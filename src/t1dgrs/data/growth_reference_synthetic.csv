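sex,gestational_week,mean_g,sd_g
female,24,964,202
female,25,1025,207
female,26,1092,213
female,27,1166,219
female,28,1249,226
female,29,1340,234
female,30,1442,243
female,31,1554,252
female,32,1680,263
female,33,1820,275
female,34,1976,288
female,35,2150,303
female,36,2345,319
female,37,2565,338
female,38,2811,359
female,39,3088,382
female,40,3400,409
female,41,3753,439
female,42,4151,473
female,43,4603,511
male,24,1001,205
male,25,1064,210
male,26,1134,216
male,27,1211,223
male,28,1297,230
male,29,1391,238
male,30,1497,247
male,31,1614,257
male,32,1744,268
male,33,1889,281
male,34,2051,294
male,35,2232,310
male,36,2435,327
male,37,2663,346
male,38,2918,368
male,39,3206,392
male,40,3530,420
male,41,3896,451
male,42,4310,486
male,43,4779,526
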