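behavior_code,intensity
continues feeding/ruminating,0
drinking,0
lying,0
necking,0
osteophagia,0
scratching,0
head to observer while ruminating,0
out of sight at beginning/following feeding,0
scanning at playback onset,0
one ear moves,1
both ears move,2
walks toward trees to continue browsing,3
isolated scanning,4
turns head while still chewing/ruminating,5
stops chewing/ruminating and looks,6
turns body posture,7
"walks closer, begins to investigate",8
moves off gradually,9
instant move out of sight/hearing,10
quick move toward other animals,11
run away,12
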