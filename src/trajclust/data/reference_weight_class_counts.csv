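weight_class,cluster1,cluster2,cluster3,cluster4,cluster5
gain_gt2,438,96,94,124,25
stable,1107,331,205,195,102
loss_2_5,2454,281,62,52,72
loss_10_15,2206,19,10,6,4
loss_gt15,549,8,0,8,2
cluster_total,11295,833,384,401,227
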