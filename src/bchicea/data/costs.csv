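# Cost tariffs in 2022 AUD per intervention arm, transcribed from the
# published cost-input table.
item,osia,baha,source
device,15125,8571,"prostheses list benefit, implant system"
replacement_sound_processor,7166,6484,"prostheses list benefit, sound processor"
surgery,1002,1002,"medicare benefits schedule, surgery + anaesthesia items"
hospitalisation,5415,5415,"public AR-DRG approximation, minor ENT intervention"
ae_management,138,138,"medicare benefits schedule, two specialist visits"
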