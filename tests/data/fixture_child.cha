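@Begin
@Languages:	eng
@Participants:	CHI Child, MOT Mother
*MOT:	what do you want to do today ?
*CHI:	I want the red ball .
*MOT:	can you tell me why ?
*CHI:	because red balls bounce .
*CHI:	she's running !
*MOT:	wow .
*CHI:	um I jumped [* gram] high
@End
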