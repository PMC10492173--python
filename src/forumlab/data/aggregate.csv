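test,sub_n,sub_mean,sub_sd,agg_n,agg_mean,agg_sd,printed_verdict,printed_p
age,661,25.5,5.3,2843,26,26.6,equivalent,<.001
total_t,552,55.9,37.9,2378,72.9,84,equivalent,<.001
dheas,381,396.5,165.2,1288,265.5,293.7,literature-lower,<.001
bmi,240,24.4,6.4,2843,27.4,28.3,equivalent,<.001
free_t,226,5.9,4.4,911,11.4,13.7,literature-higher,<.001
fpg,219,94.2,17.6,2080,89.7,90.6,equivalent,<.001
fsh,214,5.8,3.1,1883,5.9,6.4,equivalent,<.001
lh,206,12.9,13.6,1883,8.2,10.1,literature-lower,<.001
tsh,176,2.4,1.6,767,2.2,2.6,equivalent,<.001
prl,140,24.2,23.9,167,21.4,26.2,equivalent,<.001
fi,131,12.9,12,2080,14.2,18.6,equivalent,<.001
shbg,72,84.4,70.7,1423,44.5,53.8,literature-lower,<.001
amh,61,10.2,6,482,9.9,12.3,equivalent,<.001
homa_ir,57,2.1,2.4,1135,3,3.9,equivalent,.02
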